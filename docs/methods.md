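# Methods

## Shape model and superimposition

A specimen is an ordered configuration of p 3-D landmarks; point i is
homologous across specimens of the same element. Size is centroid size,
CS = √Σᵢ‖xᵢ − x̄‖². Superimposition is the *partial* Procrustes fit: every
configuration is centred and fixed at unit CS, then iteratively rotated
(proper rotations only — reflections are excluded) to the evolving consensus
until the consensus moves by less than 1e-10 or 100 iterations pass. Scale is
never re-optimised beyond the unit normalisation, so all size information is
carried by log CS alone. The reported consensus is the pointwise mean of the
aligned sample; the unit-CS-renormalised mean is used internally as the
rotation target. The summed squared deviation from the consensus is
non-increasing across iterations and is exposed as `objective_trace`.

Right-side elements can be pooled with left ones by mirroring (negating x)
before analysis; this is a pipeline toggle (`mirror`, default on) because the
correct handling depends on how the source data were digitised. Rank-deficient
rotation fits are resolved deterministically by flipping the singular vector
of the smallest singular value to force det(R) = +1.

## Thin-plate splines and bending energy

The 3-D TPS uses the radial kernel U(r) = −r (the biharmonic fundamental
solution up to a positive constant) with affine terms {1, x, y, z}. The sign
is chosen so that the bending energy, BE = Σ_d w_dᵀ K w_d summed over the
three output dimensions, is non-negative on the side-condition subspace and
zero exactly for affine maps. For a fixed source configuration the bending
energy of the map onto any target Y is the quadratic form tr(Yᵀ B Y), where B
is the upper-left p×p block of the inverse bordered system matrix
(`bending_energy_matrix`); B is symmetric positive semidefinite with constants
and the source coordinates in its null space, which makes the energy invariant
to translation and rotation of the target and quadratic in scale. Duplicate
source landmarks make the system singular and are reported by index.

## Semilandmark protocol

Surface semilandmarks are digitised once, on the template. For each specimen
a TPS is fitted from the template's fixed (anatomical + curve) landmarks to
the specimen's, the template's surface points are warped through it, and each
warped point is replaced by its exact nearest point on the specimen mesh
(vectorised point–triangle Voronoi-region test; no spatial index is needed at
these mesh sizes). Warped points farther than a snap radius (default 10% of
the mesh bounding-box diagonal) are still snapped but counted in a warning.

Sliding is the bending-energy GLS step: curve semilandmarks move only along
the central-difference tangent of their curve path, surface semilandmarks
only within the local tangent plane (barycentrically blended area-weighted
vertex normals when a mesh is present; otherwise the smallest principal
direction of up to 9 patch neighbours). With offsets t, directions U, and
sliding-point index set s, the energy is quadratic in t with Hessian
B[s,s] ⊙ (UUᵀ) and the offsets solve one linear system per specimen and
iteration; a 1e-10-scaled ridge keeps the system well posed when tangents
degenerate, and zero-tangent points stay fixed. Anatomical landmarks never
move. After sliding, curve points are re-projected onto the pre-slide curve
polyline and surface points onto the mesh; because re-projection can perturb
the unconstrained optimum, the step is accepted only if the energy does not
increase, otherwise the offsets are halved (up to 20 times) and, failing
that, the configuration is left unchanged. This guard is what makes the
recorded bending-energy trace non-increasing without exception.

The full protocol is: projection → 5 sliding iterations against the template
→ partial Procrustes consensus → 2 sliding iterations against the consensus,
with the consensus recomputed at the start of each consensus iteration. When
the data are landmark-only (no meshes), surface points keep their
tangent-plane positions after sliding; this degraded mode is supported but
the mesh-constrained protocol is the faithful one.

Fragment analyses (proximal/distal epiphyses) use template-defined index
subsets of the complete configuration — per landmark class, the most proximal
or most distal points along the bone axis, sized to the fragment census
(11/26/442 and 10/45/424). The two subsets overlap only in mid-shaft surface
points between the fourth-trochanter and anteromedial-flange anchor
landmarks. Fragments are extracted from the already-relaxed complete
configurations, mirroring the situation where fragment and complete analyses
share specimens; curve paths cannot be re-anchored inside a fragment, so
fragments are not re-slid.

## Ordination and the dimorphism test

PCA is the SVD of the centred, flattened aligned coordinates, keeping
min(n−1, 3p) components; each loading is oriented so its largest-magnitude
entry is positive, making scores reproducible to the bit. By default the scan
covers the leading axes that each explain ≥10% of total variance (PC1 always,
at most 5 axes) — the axes a morphometrician would interpret.

Each scanned axis is fitted with univariate Gaussian mixtures, G = 1..9, in
equal-variance and free-variance variants, by EM in the log domain.
Initialisation is a deterministic quantile partition plus 10 seeded random
restarts; the best final log-likelihood per (variant, G) is kept. Stopping
uses Aitken acceleration of the log-likelihood (tolerance 1e-5 relative,
≤200 iterations), converged restarts are retired from the batch, and
components that empty or collapse below 1e-12 of the data variance invalidate
their run. Model choice maximises BIC = 2·loglik − k·log n (k = 2G for equal
variance, 3G−1 for free variance); ties go to smaller G, then to the
equal-variance variant. Samples with only one or two distinct values are
returned as exact zero-variance partitions (the likelihood is unbounded
there), with a warning.

An axis is flagged *dimorphic, size-independent* when the selected G is
exactly 2 **and** the two-sided Pearson test of its scores against log CS has
p above the allometry threshold (default 0.05, configurable; no
multiple-testing correction across axes by default, with Benjamini–Hochberg
deliberately out of scope for the default path since the scanned axis set is
small and pre-registered by the variance rule). Cluster agreement between two
analyses sharing specimens is the maximum agreement over the two binary label
bijections.

Repeatability follows the operator-error protocol: three morphologically
close specimens are re-digitised n = 10 times each (noise replicates), the 30
configurations are superimposed and projected, and the separation statistic —
minimum between-specimen distance over maximum within-specimen distance in
the PC1–2 plane — exceeds 1 exactly when every replicate cloud is grouped and
isolated.

## Synthetic populations: what they emulate and what they do not

The generator emulates the statistical structure of a two-morph long-bone
sample: a parametric femur-like template (tubular shaft, medially offset
head, trochanter bumps, bilobed distal flare) carrying the full landmark
census with every landmark exactly on a mesh vertex. Morph A has a laterally
bowed shaft (quadratic offset peaking at mid-shaft, mean amplitude 3% of bone
length) with a small coupled head-inclination tweak; morph B a straight shaft
with a distally widened epiphysis (mean mediolateral multiplier 1.10). The
two features co-occur within morph by default (an uncoupled mode exists for
ablation). Mixing is 1:1.

Three choices matter for the null behaviour and were made deliberately:

* **Individual variation is absolute, not tied to the morph contrast**
  (bow-amplitude sd 0.0075, width-multiplier sd 0.025 — 25% of the default
  contrasts, i.e. ~4 pooled SDs of cluster separation). A monomorphic
  population (contrasts zeroed) therefore remains a smoothly unimodal cloud;
  without this, the "population" degenerates to template + noise, and
  per-axis mixture models on PCA of pure high-dimensional noise flag
  individual specimens as spurious clusters — a behaviour confirmed with an
  independent mixture implementation, i.e. the method working as designed on
  an unrealistic null.
* **Digitisation noise scales with each specimen's own bone length**
  (sd 0.5% of length). Constant absolute noise would make relative noise
  depend on size and let PCA chase the smallest specimens.
* **Size is decoupled from morph by construction**: the morphed shape is
  renormalised to the template's centroid size before the independent
  log-normal size factor (sd 0.06 in log units) is applied, so the morph
  displacement fields cannot leak into CS. `size_morph_coupling` re-introduces
  a controlled log-size offset between morphs for confounder experiments.

The generator does **not** emulate taphonomic distortion, ontogenetic
allometry, asymmetry, missing landmarks, or realistic cortical geometry; a
passing pipeline on synthetic data demonstrates the statistical machinery,
not the anatomical fidelity of any real population. Real inputs enter through
the same TPS/CSV/PLY interfaces.

Template dimensionality matters: with a reduced test census (e.g. 8/12/60)
noise concentrates in few dimensions and n = 40 PC1 samples are visibly
lumpy, so null experiments are run at the full census (25/99/495), where
100-seed null and recovery suites hold with margin. Problem sizes in the test
suite (n = 40 populations, 100-seed replicate suites at n = 500 for the
mixture recovery experiments) are the study conditions the package is
designed around.

## Inventory accounting

MNI per element is max over (side, fragment portion) of fragment MNE +
same-side complete MNE — a complete bone contains both portions, so same-side
complete elements add to either portion's count. This rule is an inference
that exactly reproduces the published femur (46) and tibia (61) values from
their per-side MNEs; it is documented as inferred, not quoted. Filter ledgers
subtract named removal events in order and report survivors per stage; final
totals depend only on the summed removals, order only on the staged
intermediates. Fragment eligibility criteria (preservation of the
fourth-trochanter / anteromedial-flange anchor points) are modelled as
boolean flags, not geometric tests.

## Numerical conventions and degenerate inputs

* GPA convergence 1e-10 on the consensus shift, ≤100 iterations.
* TPS warp evaluation is chunked to bound kernel-matrix memory.
* All-coincident configurations have CS 0 (warning) and cannot be
  superimposed.
* PCA requires n ≥ 3; mixture fits require n ≥ 5 finite values; the
  allometry test refuses constant inputs.
* All randomness (generator, EM restarts, repeatability noise) flows from
  explicit integer seeds; identical configs give bit-identical reports.

## Interfaces

Landmarks travel as classic TPS text blocks (`LM3=`/`ID=`) or a flat CSV
table (specimen_id, point_index, x, y, z, class, group); class/group metadata
for the TPS dialect comes from a JSON template descriptor. Meshes are
PLY/OBJ/STL via trimesh (vertex order preserved for PLY/OBJ; STL vertices
merged by exact coordinate match; zero-area faces dropped on load). Units are
opaque and never converted. The CLI subcommands exchange these same files, so
the chained stages reproduce the single-command run.
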