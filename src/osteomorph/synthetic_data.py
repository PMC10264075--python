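"""Synthetic femur-like populations with a built-in, size-independent
shape dimorphism.

The generator emulates the statistical structure a dimorphism analysis
assumes it may find in a single-species bone sample: two shape morphs in
a roughly 1:1 ratio, differing in mediolateral shaft curvature coupled
with distal-epiphysis width, with body size drawn independently of
morph, and isotropic landmark noise playing the role of digitisation
error.  Morph A carries a laterally bowed shaft (quadratic offset
peaking at mid-shaft) plus a slight head inclination; morph B a straight
shaft with a widened distal epiphysis.  The morph truth label travels
next to — never inside — the landmark data.

The template bone is a parametric surface of revolution with femur-like
features (offset head, trochanter bumps, bilobed distal flare) sampled
so that every anatomical landmark, curve semilandmark, and surface
semilandmark is exactly a mesh vertex.  Default landmark censuses are
the high-density scheme used for real long bones: 25/99/495
(anatomical/curve/surface) for a complete femur, 479-point proximal
(11/26/442) and distal (10/45/424) fragment subsets, and 23/219/483 for
a complete tibia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LandmarkConfiguration, Mesh
from .semilandmarks import DEFAULT_CENSUS, TemplateDefinition

#: Fragment censuses (anatomical, curve, surface) carved out of the
#: complete-femur template.
FRAGMENT_CENSUS = {
    "proximal": DEFAULT_CENSUS["proximal_femur"],
    "distal": DEFAULT_CENSUS["distal_femur"],
}


@dataclass
class PopulationSpec:
    """Generator settings.

    ``curvature_effect`` is the mean mid-shaft lateral bow amplitude of
    morph A as a fraction of bone length; ``width_effect`` the mean
    distal lateromedial width multiplier of morph B (morph A keeps
    1.0).  Each specimen's bow amplitude and width multiplier are drawn
    around its morph mean with sds ``individual_bow_sd`` and
    ``individual_width_sd`` — real populations carry continuous
    individual variation whether or not morphs differ, so these scales
    are absolute (not tied to the morph contrast); the defaults put the
    two morph clusters ~4 pooled standard deviations apart along the
    dimorphic direction under the default contrasts, and leave a
    monomorphic population smoothly unimodal rather than a pure-noise
    delta.  ``noise_sd`` is the isotropic per-landmark
    digitisation noise as a fraction of bone length; sizes are
    log-normal, ``size_morph_coupling`` adds ±coupling/2 to the log size
    by morph (0 = size-independent dimorphism).  With ``coupled``
    (default) the bow and the narrow epiphysis always co-occur;
    uncoupled mode draws the two features independently for ablation.
    """

    n: int = 40
    mixing: float = 0.5
    curvature_effect: float = 0.03
    width_effect: float = 1.10
    individual_bow_sd: float = 0.0075
    individual_width_sd: float = 0.025
    noise_sd: float = 0.005
    size_log_mean: float = 0.0
    size_log_sd: float = 0.06
    size_morph_coupling: float = 0.0
    coupled: bool = True
    with_meshes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")
        if self.noise_sd < 0 or self.size_log_sd < 0:
            raise ValueError("scales must be non-negative")
        if self.width_effect <= 0:
            raise ValueError("width_effect must be positive")


@dataclass
class SyntheticSpecimen:
    """A generated specimen; ``truth`` is ground truth the pipeline
    never reads (morph label, true size factor)."""

    config: LandmarkConfiguration
    mesh: Mesh | None
    truth: dict


# ---------------------------------------------------------------------------
# parametric bone surface
# ---------------------------------------------------------------------------

def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bone_surface_point(t, theta, length, element):
    """Surface of the idealised bone at axial fraction t (0 = distal,
    1 = proximal) and azimuth theta (0 = medial, +x)."""
    t = np.asarray(t, float)
    theta = np.asarray(theta, float)
    r0 = 0.055 * length
    # distal flare, bilobed (condyles wide mediolaterally)
    distal = _smoothstep((0.18 - t) / 0.18)
    r = 1.0 + 0.55 * distal + 0.35 * distal * np.cos(theta) ** 2
    if element == "complete_femur":
        # proximal flare with greater-trochanter bump (lateral, theta=pi)
        prox = _smoothstep((t - 0.80) / 0.20)
        ang = np.arctan2(np.sin(theta - np.pi), np.cos(theta - np.pi))  # signed angle to lateral
        r = r + 0.45 * prox + 0.30 * prox * np.exp(-(ang**2) / 0.5)
        cx = 0.9 * r0 * _smoothstep((t - 0.85) / 0.15)  # head offset, medial
    else:  # tibia-like: flat proximal plateau, no offset head
        prox = _smoothstep((t - 0.82) / 0.18)
        r = r + 0.55 * prox + 0.25 * prox * np.sin(theta) ** 2
        cx = np.zeros_like(t) if t.shape else 0.0
    x = cx + r0 * r * np.cos(theta)
    y = r0 * r * np.sin(theta)
    z = length * t
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def _spread(n_pool: int, k: int) -> np.ndarray:
    """k unique, sorted indices spread evenly over range(n_pool)."""
    if k > n_pool:
        raise ValueError(f"cannot pick {k} distinct items from {n_pool}")
    idx = np.round(np.linspace(0, n_pool - 1, k)).astype(int)
    for i in range(1, k):  # enforce strict monotonicity after rounding
        if idx[i] <= idx[i - 1]:
            idx[i] = idx[i - 1] + 1
    if idx[-1] >= n_pool:
        raise ValueError("index spread overflow")
    return idx


# (theta index is out of N_THETA; levels are snapped to even values so
# anatomical/curve points can never collide with surface rows, which
# occupy odd levels)
N_THETA = 33
_RIDGE_THETA = (0, 11, 22)

_FEMUR_NAMED = [
    # proximal group: exactly 11 points at or above the fourth trochanter
    ("head_apex", 0.978, 2),
    ("head_center", 0.978, 30),
    ("greater_trochanter", 0.935, 16),
    ("femoral_neck", 0.935, 5),
    ("proximolateral", 0.913, 25),
    ("proximomedial", 0.913, 8),
    ("lesser_trochanter", 0.891, 5),
    ("fourth_trochanter", 0.860, 16),
    # mid-shaft group: in neither fragment subset
    ("shaft_upper", 0.650, 5),
    ("shaft_mid_lat", 0.550, 16),
    ("shaft_mid_med", 0.450, 28),
    ("shaft_lower", 0.350, 8),
    # distal group: exactly 10 points at or below the anteromedial flange
    ("anteromedial_flange", 0.087, 5),
    ("distolateral_2", 0.065, 19),
    ("distomedial_2", 0.065, 31),
    ("posterior_intercondylar", 0.043, 8),
    ("anterior_intercondylar", 0.043, 25),
    ("medial_condyle", 0.022, 2),
    ("lateral_condyle", 0.022, 16),
]


def build_ideal_femur(
    counts=None,
    element: str = "complete_femur",
    length: float = 400.0,
    with_mesh: bool = True,
) -> TemplateDefinition:
    """Parametric template bone with the given (anatomical, curve,
    surface) landmark counts (default: the element's census).

    Landmarks sit exactly on mesh vertices: 3 longitudinal curve ridges
    with anatomical endpoints, a proximal-to-distal grid of surface
    semilandmarks in 11 angular columns, and anatomical landmarks at
    named femoral loci (head, trochanters, condyles, anteromedial
    flange) padded with epiphyseal ring points as needed.
    """
    if counts is None:
        counts = DEFAULT_CENSUS[element]
    n_anat, n_curve, n_surf = counts
    n_ridges = 3
    if n_anat < 2 * n_ridges:
        raise ValueError("need at least 6 anatomical landmarks for the 3 curve ridges")
    if n_curve < n_ridges or n_surf < 11:
        raise ValueError("counts too small to populate curves and surface grid")
    per_ridge = [n_curve // n_ridges + (1 if r < n_curve % n_ridges else 0) for r in range(n_ridges)]
    n_scols = 11
    n_srows = -(-n_surf // n_scols)
    n_levels = 2 * max(n_srows, max(per_ridge)) + 3
    top = n_levels - 1
    if top % 2:
        n_levels += 1
        top += 1
    t_of = lambda level: level / top

    used = set()

    def claim(level, th):
        key = (int(level), int(th))
        if key in used:
            raise RuntimeError(f"duplicate landmark locus {key}")
        used.add(key)
        return key

    def snap_even(frac):
        lvl = int(round(frac * top / 2.0)) * 2
        return min(max(lvl, 0), top)

    # --- anatomical landmarks ---------------------------------------
    anat_loci = []
    for th in _RIDGE_THETA:  # ridge proximal endpoints
        anat_loci.append(claim(top, th))
    for th in _RIDGE_THETA:  # ridge distal endpoints
        anat_loci.append(claim(0, th))
    named = _FEMUR_NAMED if element == "complete_femur" else []
    for _, frac, th in named:
        if len(anat_loci) >= n_anat:
            break
        anat_loci.append(claim(snap_even(frac), th))
    # pad with epiphyseal ring loci, proximal and distal alternately
    pad_pool = [
        (lvl, th)
        for lvl in (top - 2, 2, top - 4, 4, top - 6, 6, top - 8, 8)
        for th in (2, 5, 8, 14, 16, 19, 25, 28, 31)
    ]
    for lvl, th in pad_pool:
        if len(anat_loci) >= n_anat:
            break
        if (lvl, th) not in used:
            anat_loci.append(claim(lvl, th))
    if len(anat_loci) < n_anat:
        raise ValueError(f"cannot place {n_anat} distinct anatomical landmarks")

    # --- curve semilandmarks: even levels strictly inside ------------
    even_pool = np.arange(2, top - 1, 2)
    curve_loci, curve_paths_local = [], []
    for r, th in enumerate(_RIDGE_THETA):
        levels = even_pool[_spread(len(even_pool), per_ridge[r])]
        start = len(curve_loci)
        for lvl in levels:  # distal -> proximal along the ridge
            if (lvl, th) in used:
                raise RuntimeError(f"curve locus collision at {(lvl, th)}")
            used.add((int(lvl), int(th)))
            curve_loci.append((int(lvl), int(th)))
        curve_paths_local.append((r, start, per_ridge[r]))

    # --- surface semilandmarks: odd levels, proximal-first rows ------
    odd_pool = np.arange(1, top, 2)[::-1]  # descending t
    rows = odd_pool[_spread(len(odd_pool), n_srows)]  # proximal-first rows
    scols = np.arange(0, 3 * n_scols, 3)
    surf_loci = []
    for lvl in rows:
        for th in scols:
            if len(surf_loci) >= n_surf:
                break
            surf_loci.append((int(lvl), int(th)))

    # --- assemble configuration --------------------------------------
    theta_of = lambda th: 2 * np.pi * th / N_THETA
    all_loci = anat_loci + curve_loci + surf_loci
    pts = np.array(
        [_bone_surface_point(t_of(lvl), theta_of(th), length, element) for lvl, th in all_loci]
    )
    classes = np.array(
        ["anatomical"] * n_anat + ["curve_semi"] * n_curve + ["surface_semi"] * n_surf
    )
    group = np.full(len(pts), -1, dtype=int)
    curves = []
    for r, start, count in curve_paths_local:
        semi_idx = n_anat + start + np.arange(count)
        group[semi_idx] = r
        curves.append(np.concatenate([[3 + r], semi_idx, [r]]))  # distal end, semis, proximal end
    surf_base = n_anat + n_curve
    for k, (lvl, th) in enumerate(surf_loci):
        group[surf_base + k] = int(th // 3) // 4  # 3 angular-sector patches

    config = LandmarkConfiguration(
        specimen_id="template",
        element=element,
        side="left",
        points=pts,
        classes=classes,
        group=group,
    )
    mesh = _build_bone_mesh(length, element, n_levels, used_loci=all_loci) if with_mesh else None
    patches = {
        int(pid): surf_base + np.flatnonzero(group[surf_base:] == pid)
        for pid in np.unique(group[surf_base:])
    }
    return TemplateDefinition(config=config, mesh=mesh, curves=curves, patches=patches)


def _build_bone_mesh(length, element, n_levels, used_loci):
    top = n_levels - 1
    levels = np.arange(n_levels)
    thetas = 2 * np.pi * np.arange(N_THETA) / N_THETA
    tt, th = np.meshgrid(levels / top, thetas, indexing="ij")
    verts = _bone_surface_point(tt.ravel(), th.ravel(), length, element).reshape(-1, 3)
    faces = []
    for i in range(n_levels - 1):
        for j in range(N_THETA):
            a = i * N_THETA + j
            b = i * N_THETA + (j + 1) % N_THETA
            c = (i + 1) * N_THETA + j
            d = (i + 1) * N_THETA + (j + 1) % N_THETA
            faces.append((a, b, d))
            faces.append((a, d, c))
    apex_d = len(verts)
    apex_p = len(verts) + 1
    cx_d = verts[:N_THETA].mean(axis=0)
    cx_p = verts[-N_THETA:].mean(axis=0)
    verts = np.vstack([verts, cx_d - [0, 0, 0.02 * length], cx_p + [0, 0, 0.02 * length]])
    for j in range(N_THETA):
        faces.append((apex_d, (j + 1) % N_THETA, j))
        faces.append((apex_p, (n_levels - 1) * N_THETA + j, (n_levels - 1) * N_THETA + (j + 1) % N_THETA))
    return Mesh(verts, np.asarray(faces, int)).drop_degenerate_faces()


# ---------------------------------------------------------------------------
# morph displacement fields
# ---------------------------------------------------------------------------

def _apply_morph(points: np.ndarray, length: float, bow_amp: float,
                 width_mult: float) -> np.ndarray:
    """Displace a point array by continuous morph features: a lateral
    quadratic shaft bow of amplitude *bow_amp* (fraction of length,
    with a coupled head-inclination tweak) and a distal lateromedial
    widening by *width_mult*.  Vectorised; applies to landmark arrays
    and mesh vertices alike."""
    pts = points.copy()
    t = np.clip(pts[:, 2] / length, 0.0, 1.0)
    if bow_amp != 0.0:
        # lateral (-x) quadratic bow peaking at mid-shaft
        pts[:, 0] -= bow_amp * length * 4.0 * t * (1.0 - t)
        # ventromedial head-inclination tweak above the neck
        u = np.clip((t - 0.85) / 0.15, 0.0, None)
        pts[:, 0] += 0.4 * bow_amp * length * u**2
        pts[:, 1] -= 0.2 * bow_amp * length * u**2
    if width_mult != 1.0:
        # distal lateromedial widening about the sagittal plane
        w = 1.0 + (width_mult - 1.0) * _smoothstep((0.2 - t) / 0.2)
        pts[:, 0] *= w
    return pts


def _cs(pts: np.ndarray) -> float:
    c = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def generate_population(spec: PopulationSpec, template: TemplateDefinition) -> list:
    """Draw a population of :class:`SyntheticSpecimen` from *spec*.

    Morph B is drawn with probability ``mixing``; size factors are
    log-normal and independent of morph unless ``size_morph_coupling``
    is non-zero.  Fully reproducible from ``spec.seed``.
    """
    if spec.n < 2:
        raise ValueError("population needs at least 2 specimens")
    rng = np.random.default_rng(spec.seed)
    length = float(np.ptp(template.config.points[:, 2]))
    out = []
    for i in range(spec.n):
        is_b = bool(rng.random() < spec.mixing)
        if spec.coupled:
            bow, wide = (not is_b), is_b
        else:
            bow = not is_b
            wide = bool(rng.random() < spec.mixing)
        # individual variation of the features about the morph means
        bow_amp = rng.normal(spec.curvature_effect if bow else 0.0,
                             spec.individual_bow_sd)
        width_mult = rng.normal(spec.width_effect if wide else 1.0,
                                spec.individual_width_sd)
        log_s = rng.normal(spec.size_log_mean, spec.size_log_sd)
        log_s += spec.size_morph_coupling * (0.5 if is_b else -0.5)
        s = float(np.exp(log_s))
        pts = _apply_morph(template.config.points, length, bow_amp, width_mult)
        # renormalise to the template's centroid size so that size is
        # decoupled from morph by construction (the bow/width fields
        # would otherwise leak a small systematic CS offset)
        centroid = pts.mean(axis=0)
        pts = centroid + (pts - centroid) * (_cs(template.config.points) / _cs(pts))
        pts = pts * s
        # digitisation noise scales with the specimen's own bone length
        pts = pts + rng.normal(0.0, spec.noise_sd * length * s, pts.shape)
        config = template.config.with_points(pts, specimen_id=f"synth_{i:03d}")
        mesh = None
        if spec.with_meshes and template.mesh is not None:
            mv = _apply_morph(template.mesh.vertices, length, bow_amp, width_mult) * s
            mesh = Mesh(mv, template.mesh.faces.copy())
        out.append(
            SyntheticSpecimen(
                config=config,
                mesh=mesh,
                truth={"morph": int(is_b), "bow": int(bow), "wide": int(wide),
                       "bow_amp": float(bow_amp), "width_mult": float(width_mult),
                       "size_factor": s, "index": i},
            )
        )
    return out


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def fragment_indices(template: TemplateDefinition, portion: str, counts=None) -> np.ndarray:
    """Template point indices of a fragment, in template order.

    Per landmark class, the *counts* most proximal (``portion ==
    'proximal'``) or most distal points along the bone axis are taken;
    the two fragment subsets therefore overlap only in mid-shaft points
    between the fourth-trochanter and anteromedial-flange anchors.
    """
    if portion not in ("proximal", "distal"):
        raise ValueError(f"unknown portion {portion!r}")
    if counts is None:
        if template.config.element != "complete_femur":
            raise ValueError("default fragment censuses exist only for the complete femur")
        counts = FRAGMENT_CENSUS[portion]
    z = template.config.points[:, 2]
    picked = []
    for n_take, cls in zip(counts, ("anatomical", "curve_semi", "surface_semi")):
        members = np.flatnonzero(template.config.classes == cls)
        order = members[np.argsort(-z[members], kind="stable")]
        sub = order[:n_take] if portion == "proximal" else order[-n_take:]
        picked.append(np.sort(sub))
    return np.concatenate(picked)


def extract_fragment(config: LandmarkConfiguration, portion: str,
                     template: TemplateDefinition, counts=None) -> LandmarkConfiguration:
    """Fragment configuration: the template-defined index subset of a
    complete configuration (point order preserved, so fragments remain
    homologous across specimens)."""
    idx = fragment_indices(template, portion, counts)
    element = f"{portion}_femur" if config.element == "complete_femur" else config.element
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        element=element if element in ("proximal_femur", "distal_femur") else config.element,
        side=config.side,
        points=config.points[idx].copy(),
        classes=config.classes[idx],
        group=config.group[idx],
    )
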