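"""Procrustes superimposition and 3D thin-plate splines.

Shape here means landmark geometry with location, orientation and scale
removed.  Size is measured by centroid size (CS), the square root of the
summed squared distances of the landmarks from their centroid; the
superimposition is the *partial* Procrustes fit — every configuration is
fixed at unit CS and only rotated/translated — so that size enters the
downstream analysis solely through log CS.

The thin-plate spline (TPS) is the interpolating deformation between two
homologous point sets.  In 3D the radial kernel is the biharmonic
fundamental solution, taken here as U(r) = -r so that the bending energy
(the quadratic roughness of the non-affine part, summed over the three
output dimensions) is non-negative and vanishes exactly on affine maps.
The TPS serves two roles: measuring bending energy during semilandmark
sliding, and warping template meshes onto reconstructed shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import LandmarkConfiguration


# ---------------------------------------------------------------------------
# size and rotation
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared distances to the centroid.

    Accepts a :class:`LandmarkConfiguration` or a bare (p, 3) array.
    Scales linearly with the configuration (CS(k·X) = k·CS(X)).
    """
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if len(pts) < 2:
        raise ValueError("centroid size needs at least 2 points")
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all points coincident (CS = 0)", stacklevel=2)
    return cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||A @ R - B||² (reflections excluded).

    Both point sets must be centered and of equal length.  When the
    cross-covariance is rank deficient the tie is broken by flipping the
    singular vector of the smallest singular value to force det(R)=+1.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(3)
    if np.linalg.det(U @ Vt) < 0:
        D[2, 2] = -1.0  # smallest singular value is last in numpy's ordering
    return U @ D @ Vt


def procrustes_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Root-sum-square distance between A and B after centering, unit-CS
    scaling, and optimal proper rotation of A onto B."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Ac /= np.sqrt(np.sum(Ac**2))
    Bc /= np.sqrt(np.sum(Bc**2))
    R = optimal_rotation(Ac, Bc)
    return float(np.linalg.norm(Ac @ R - Bc))


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class GPAResult:
    """Partial-Procrustes superimposition of a sample.

    ``aligned`` holds the superimposed (p, 3) coordinates per specimen,
    each centered at the origin and scaled to unit centroid size;
    ``consensus`` is their pointwise mean.  ``centroid_sizes`` are the
    pre-scaling sizes, the study's size variable.
    """

    aligned: list
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list
    iterations: int
    converged: bool
    objective_trace: list = field(default_factory=list)

    @property
    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def n_specimens(self) -> int:
        return len(self.aligned)


def _as_point_arrays(configs):
    if all(isinstance(c, LandmarkConfiguration) for c in configs):
        elements = {c.element for c in configs}
        if len(elements) > 1:
            raise ValueError(f"mixed element types in GPA input: {sorted(elements)}")
        ids = [c.specimen_id for c in configs]
        arrays = [c.points for c in configs]
    else:
        ids = [f"config_{i}" for i in range(len(configs))]
        arrays = [np.asarray(c, float) for c in configs]
    p = {a.shape for a in arrays}
    if len(p) > 1:
        raise ValueError(f"configurations differ in point count: {sorted(p)}")
    return arrays, ids


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Generalized (partial) Procrustes analysis.

    Each configuration is centered and scaled to unit centroid size,
    then iteratively rotated to the evolving consensus (itself re-centered
    and rescaled to unit CS each round) until the consensus moves by less
    than *tol* or *max_iter* rounds pass.  The summed squared deviation
    from the consensus is non-increasing across iterations.
    """
    arrays, ids = _as_point_arrays(configs)
    if len(arrays) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(a) for a in arrays])
    if np.any(sizes == 0):
        raise ValueError("cannot superimpose a fully degenerate (CS = 0) configuration")
    X = [(a - a.mean(axis=0)) / s for a, s in zip(arrays, sizes)]

    consensus = X[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        X = [x @ optimal_rotation(x, consensus) for x in X]
        new_consensus = np.mean(X, axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt(np.sum(new_consensus**2))
        if norm == 0:
            raise ValueError("degenerate consensus (configurations cancel out)")
        new_consensus /= norm
        trace.append(float(sum(np.sum((x - new_consensus) ** 2) for x in X)))
        shift = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    return GPAResult(
        aligned=X,
        # the unit-CS consensus is only the internal rotation target;
        # the reported consensus is the pointwise mean of the aligned sample
        consensus=np.mean(X, axis=0),
        centroid_sizes=sizes,
        specimen_ids=ids,
        iterations=it,
        converged=converged,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------

def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # 3D biharmonic spline; the sign makes wᵀKw >= 0 under the side conditions
    return -r


def _kernel_matrix(source: np.ndarray, query: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(query[:, None, :] - source[None, :, :], axis=2)
    return _tps_kernel(d)


@dataclass
class TPSModel:
    """Fitted 3D thin-plate-spline deformation source → target.

    ``affine`` is the 4×3 matrix of the affine part ([1, x, y, z] row
    convention); ``weights`` the (p, 3) non-affine kernel weights, which
    satisfy the side conditions Wᵀ[1 | X] = 0.  ``bending_energy`` is
    Σ_d w_dᵀ K w_d, zero iff the map is affine.
    """

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the interpolating TPS carrying *source* landmarks onto *target*.

    Raises if two source landmarks coincide (singular kernel system).
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape:
        raise ValueError(f"source {source.shape} and target {target.shape} differ")
    p = len(source)
    if p < 4:
        raise ValueError("3D TPS needs at least 4 landmarks")
    d = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=2)
    dup = np.argwhere((d < 1e-12) & ~np.eye(p, dtype=bool))
    if len(dup):
        i, j = dup[0]
        raise ValueError(f"duplicated source landmarks {i} and {j}: TPS system singular")
    K = _tps_kernel(d)
    P = np.hstack([np.ones((p, 1)), source])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    rhs = np.vstack([target, np.zeros((4, 3))])
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"TPS system singular: {exc}") from exc
    W = sol[:p]
    A = sol[p:]
    be = float(np.einsum("id,ij,jd->", W, K, W))
    return TPSModel(source=source, target=target, affine=A, weights=W, bending_energy=max(be, 0.0))


def tps_warp(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary 3D query points."""
    q = np.atleast_2d(np.asarray(points, float))
    out = np.empty_like(q)
    P = np.hstack([np.ones((len(q), 1)), q])
    # chunk the kernel evaluation to bound memory for large meshes
    step = max(1, int(2e7) // max(len(model.source), 1))
    for lo in range(0, len(q), step):
        hi = min(lo + step, len(q))
        U = _kernel_matrix(model.source, q[lo:hi])
        out[lo:hi] = P[lo:hi] @ model.affine + U @ model.weights
    return out.reshape(np.shape(points))


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """Bending-energy matrix B of a source configuration.

    For any target Y the TPS bending energy source → Y equals
    tr(Yᵀ B Y); B is the upper-left p×p block of the inverse of the
    bordered TPS system matrix, symmetric positive semidefinite with the
    constants and the source coordinates in its null space.  This is the
    quadratic form the sliding step minimises.
    """
    source = np.asarray(source, float)
    p = len(source)
    K = _kernel_matrix(source, source)
    P = np.hstack([np.ones((p, 1)), source])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    rhs = np.zeros((p + 4, p))
    rhs[:p] = np.eye(p)
    B = np.linalg.solve(L, rhs)[:p]
    return 0.5 * (B + B.T)
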