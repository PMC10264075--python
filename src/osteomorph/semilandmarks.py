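"""Template-driven semilandmark placement and sliding relaxation.

Semilandmarks carry no pointwise homology of their own: a point midway
along a bone shaft is only comparable across specimens after it has been
allowed to *slide* along its curve or surface until the deformation
relating specimen to reference is as smooth as possible.  Smoothness is
measured by thin-plate-spline bending energy, and the slide is the
generalized-least-squares step: each curve semilandmark moves only along
its local tangent, each surface semilandmark only within its local
tangent plane, with the tangential offsets solving the linear system
that minimises the bending energy of the reference → specimen TPS.
Anatomical landmarks never move.

The full protocol mirrors standard high-density morphometrics practice:

1. surface semilandmarks digitised once on a template specimen are
   projected onto every other specimen through a TPS fitted on the fixed
   (anatomical + curve) landmarks, then snapped to the specimen mesh;
2. five sliding iterations against the template configuration;
3. a partial Procrustes consensus is computed and two further sliding
   iterations run against it (the consensus is recomputed each
   iteration).

After each slide, semilandmarks are re-projected onto the specimen's
curve polyline or mesh surface; when no mesh is available (landmark-only
data) surface points keep their tangent-plane positions.  A backtracking
step-halving guard keeps the bending-energy trace non-increasing even
when re-projection perturbs the unconstrained optimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry_core import bending_energy_matrix, gpa, tps_fit, tps_warp
from .io_formats import LandmarkConfiguration, Mesh

#: Landmark census (anatomical, curve, surface) per element type.
DEFAULT_CENSUS = {
    "complete_femur": (25, 99, 495),
    "proximal_femur": (11, 26, 442),
    "distal_femur": (10, 45, 424),
    "complete_tibia": (23, 219, 483),
}


@dataclass
class TemplateDefinition:
    """The reference specimen driving projection and sliding.

    ``curves`` are ordered index paths into the template configuration;
    each path must start and end at an anatomical landmark, with curve
    semilandmarks in between.  ``patches`` map a patch id to the indices
    of the surface semilandmarks sliding on that patch.
    """

    config: LandmarkConfiguration
    mesh: Mesh | None = None
    curves: list = field(default_factory=list)
    patches: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cls = self.config.classes
        for path in self.curves:
            path = np.asarray(path, int)
            if cls[path[0]] != "anatomical" or cls[path[-1]] != "anatomical":
                raise ValueError("curve path must start and end at an anatomical landmark")
            if not np.all(cls[path[1:-1]] == "curve_semi"):
                raise ValueError("curve path interior must be curve semilandmarks")

    @property
    def anatomical_indices(self) -> np.ndarray:
        return np.flatnonzero(self.config.classes == "anatomical")

    @property
    def curve_indices(self) -> np.ndarray:
        return np.flatnonzero(self.config.classes == "curve_semi")

    @property
    def surface_indices(self) -> np.ndarray:
        return np.flatnonzero(self.config.classes == "surface_semi")

    @property
    def fixed_indices(self) -> np.ndarray:
        """Anatomical + curve landmark indices (the non-patch points)."""
        return np.flatnonzero(self.config.classes != "surface_semi")

    def class_counts(self) -> tuple:
        c = self.config.class_counts()
        return (c["anatomical"], c["curve_semi"], c["surface_semi"])

    def validate_census(self, census: dict = DEFAULT_CENSUS) -> None:
        expected = census.get(self.config.element)
        if expected is None:
            raise ValueError(f"no census configured for element {self.config.element!r}")
        got = self.class_counts()
        if tuple(expected) != got:
            raise ValueError(
                f"{self.config.element}: class counts {got} do not match census {tuple(expected)}"
            )

    # --- descriptor persistence (JSON) ---------------------------------
    def to_descriptor(self) -> dict:
        return {
            "element": self.config.element,
            "classes": self.config.classes.tolist(),
            "group": self.config.group.tolist(),
            "curves": [np.asarray(c, int).tolist() for c in self.curves],
            "patches": {str(k): np.asarray(v, int).tolist() for k, v in self.patches.items()},
        }

    def save_descriptor(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_descriptor()))


@dataclass
class SlidingResult:
    """Outcome of a relaxation run: relaxed configurations plus the
    per-iteration total bending energy (element 0 is the pre-slide
    energy; the trace is non-increasing up to 1e-9 relative slack)."""

    configs: list
    bending_energy_trace: list
    iterations_run: int


# ---------------------------------------------------------------------------
# nearest point on a triangulated surface
# ---------------------------------------------------------------------------

def closest_point_on_mesh(mesh: Mesh, points: np.ndarray):
    """Exact nearest point on any triangle of *mesh* for each query.

    Returns ``(closest (n,3), distance (n,), face_index (n,))``.  Uses
    the barycentric clamping construction, vectorised over all
    point–triangle pairs in memory-bounded chunks.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty_like(points)
    dist = np.empty(len(points))
    fidx = np.empty(len(points), dtype=int)
    chunk = max(1, int(4e6) // max(mesh.n_faces, 1))
    for lo in range(0, len(points), chunk):
        q = points[lo : lo + chunk][:, None, :]  # (n, 1, 3)
        ap = q - a
        d1 = np.einsum("mk,nmk->nm", ab, ap)
        d2 = np.einsum("mk,nmk->nm", ac, ap)
        bp = q - b
        d3 = np.einsum("mk,nmk->nm", ab, bp)
        d4 = np.einsum("mk,nmk->nm", ac, bp)
        cp = q - c
        d5 = np.einsum("mk,nmk->nm", ab, cp)
        d6 = np.einsum("mk,nmk->nm", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        with np.errstate(divide="ignore", invalid="ignore"):
            v_ab = np.nan_to_num(np.clip(d1 / (d1 - d3), 0.0, 1.0))
            w_ac = np.nan_to_num(np.clip(d2 / (d2 - d6), 0.0, 1.0))
            w_bc = np.nan_to_num(
                np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
            )
            denom = va + vb + vc
            v_in = np.nan_to_num(vb / denom)
            w_in = np.nan_to_num(vc / denom)

        # Voronoi-region branches of the standard point/triangle test,
        # applied lowest-priority first so earlier regions overwrite later.
        cand = a + v_in[..., None] * ab + w_in[..., None] * ac  # face interior
        edge_bc = b + w_bc[..., None] * (c - b)
        edge_ac = a + w_ac[..., None] * ac
        edge_ab = a + v_ab[..., None] * ab
        cand = np.where(
            ((va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0))[..., None], edge_bc, cand
        )
        cand = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None], edge_ac, cand)
        cand = np.where(
            ((d6 >= 0) & (d5 <= d6))[..., None], np.broadcast_to(c, cand.shape), cand
        )
        cand = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None], edge_ab, cand)
        cand = np.where(
            ((d3 >= 0) & (d4 <= d3))[..., None], np.broadcast_to(b, cand.shape), cand
        )
        cand = np.where(
            ((d1 <= 0) & (d2 <= 0))[..., None], np.broadcast_to(a, cand.shape), cand
        )

        d2q = np.sum((cand - q) ** 2, axis=2)
        best = np.argmin(d2q, axis=1)
        rows = np.arange(len(best))
        out[lo : lo + chunk] = cand[rows, best]
        dist[lo : lo + chunk] = np.sqrt(d2q[rows, best])
        fidx[lo : lo + chunk] = best
    return out, dist, fidx


def _closest_point_on_polyline(poly: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Nearest point on the open polyline *poly* for each query point."""
    seg_a = poly[:-1]
    seg_d = poly[1:] - poly[:-1]
    len2 = np.sum(seg_d**2, axis=1)
    len2[len2 == 0] = 1.0
    q = np.atleast_2d(points)[:, None, :]
    t = np.clip(np.einsum("nmk,mk->nm", q - seg_a, seg_d) / len2, 0.0, 1.0)
    cand = seg_a + t[..., None] * seg_d
    d2 = np.sum((cand - q) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    return cand[np.arange(len(best)), best]


# ---------------------------------------------------------------------------
# patch projection
# ---------------------------------------------------------------------------

def project_patch(
    template: TemplateDefinition,
    specimen_mesh: Mesh,
    specimen_fixed: LandmarkConfiguration,
    snap_radius: float | None = None,
) -> LandmarkConfiguration:
    """Transfer the template's surface semilandmarks onto a specimen.

    A TPS is fitted from the template's fixed (anatomical + curve)
    landmarks to the specimen's, the template surface semilandmarks are
    warped through it, and each warped point is replaced by its nearest
    point on the specimen mesh.  Warped points farther than
    *snap_radius* (default: 10% of the mesh bounding-box diagonal) from
    the surface are still snapped, but counted in a warning.
    """
    if specimen_mesh is None or specimen_mesh.n_faces == 0:
        raise ValueError("patch projection requires a non-empty specimen mesh")
    fixed_idx = template.fixed_indices
    if specimen_fixed.n_points != len(fixed_idx):
        raise ValueError(
            f"specimen has {specimen_fixed.n_points} fixed landmarks, "
            f"template expects {len(fixed_idx)}"
        )
    model = tps_fit(template.config.points[fixed_idx], specimen_fixed.points)
    surf_idx = template.surface_indices
    warped = tps_warp(model, template.config.points[surf_idx])
    snapped, dist, _ = closest_point_on_mesh(specimen_mesh, warped)
    if snap_radius is None:
        bbox = specimen_mesh.vertices.max(axis=0) - specimen_mesh.vertices.min(axis=0)
        snap_radius = 0.1 * float(np.linalg.norm(bbox))
    n_far = int(np.sum(dist > snap_radius))
    if n_far:
        warnings.warn(
            f"{specimen_fixed.specimen_id}: {n_far} warped surface points farther than "
            f"snap radius {snap_radius:.3g} from the mesh",
            stacklevel=2,
        )
    pts = np.empty((template.config.n_points, 3))
    pts[fixed_idx] = specimen_fixed.points
    pts[surf_idx] = snapped
    return LandmarkConfiguration(
        specimen_fixed.specimen_id,
        template.config.element,
        specimen_fixed.side,
        pts,
        template.config.classes,
        template.config.group,
    )


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------

def _curve_tangents(template: TemplateDefinition, pts: np.ndarray):
    """Unit tangents (central differences along the path) for every
    curve semilandmark, as ``{point_index: tangent}``."""
    tangents = {}
    for path in template.curves:
        path = np.asarray(path, int)
        for j in range(1, len(path) - 1):
            t = pts[path[j + 1]] - pts[path[j - 1]]
            n = np.linalg.norm(t)
            tangents[int(path[j])] = t / n if n > 0 else np.zeros(3)
    return tangents


def _orthonormal_tangent_pair(normal: np.ndarray) -> tuple:
    n = np.linalg.norm(normal)
    if n == 0:
        return np.zeros(3), np.zeros(3)
    normal = normal / n
    seed = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    t1 = seed - np.dot(seed, normal) * normal
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(normal, t1)


def _surface_tangents(template: TemplateDefinition, pts: np.ndarray, mesh: Mesh | None):
    """Per surface semilandmark, two orthonormal tangent-plane vectors.

    With a mesh: the normal is the barycentric blend of area-weighted
    vertex normals on the enclosing (nearest) triangle.  Without: the
    normal is the smallest principal direction of the point's patch
    neighbourhood.
    """
    surf_idx = template.surface_indices
    tangents = {}
    if mesh is not None and mesh.n_faces > 0:
        closest, _, fidx = closest_point_on_mesh(mesh, pts[surf_idx])
        vnorm = mesh.vertex_normals()
        for k, i in enumerate(surf_idx):
            tri = mesh.faces[fidx[k]]
            v = mesh.vertices[tri]
            # barycentric weights of the snapped point in its triangle
            T = np.column_stack([v[1] - v[0], v[2] - v[0]])
            rhs = closest[k] - v[0]
            try:
                uv, *_ = np.linalg.lstsq(T, rhs, rcond=None)
            except np.linalg.LinAlgError:
                uv = np.array([1 / 3, 1 / 3])
            w = np.array([1 - uv[0] - uv[1], uv[0], uv[1]])
            normal = w @ vnorm[tri]
            tangents[int(i)] = _orthonormal_tangent_pair(normal)
    else:
        group = template.config.group
        for pid in np.unique(group[surf_idx]):
            members = surf_idx[group[surf_idx] == pid]
            if len(members) < 3:
                warnings.warn(
                    f"patch {pid}: fewer than 3 points, surface semilandmarks held fixed",
                    stacklevel=2,
                )
                for i in members:
                    tangents[int(i)] = (np.zeros(3), np.zeros(3))
                continue
            P = pts[members]
            for i in members:
                d = np.sum((P - pts[i]) ** 2, axis=1)
                near = members[np.argsort(d)[: min(9, len(members))]]
                Q = pts[near] - pts[near].mean(axis=0)
                _, _, Vt = np.linalg.svd(Q, full_matrices=False)
                tangents[int(i)] = (Vt[0], Vt[1])
    return tangents


def slide_iteration(
    config: LandmarkConfiguration,
    reference: np.ndarray,
    template: TemplateDefinition,
    specimen_mesh: Mesh | None = None,
    bending_matrix: np.ndarray | None = None,
) -> LandmarkConfiguration:
    """One bending-energy-minimising slide of *config* against *reference*.

    Solves the tangential generalized-least-squares problem, applies the
    offsets, re-projects semilandmarks onto the curve polyline / mesh,
    and backtracks (halving the offsets) if re-projection would raise
    the bending energy; anatomical landmarks are untouched.
    """
    reference = np.asarray(reference, float)
    Y0 = config.points
    if reference.shape != Y0.shape:
        raise ValueError("configuration and reference are not homologous")
    B = bending_matrix if bending_matrix is not None else bending_energy_matrix(reference)

    ctan = _curve_tangents(template, Y0)
    stan = _surface_tangents(template, Y0, specimen_mesh)
    idx, dirs = [], []
    for i, t in ctan.items():
        idx.append(i)
        dirs.append(t)
    for i, (t1, t2) in stan.items():
        idx.append(i)
        dirs.append(t1)
        idx.append(i)
        dirs.append(t2)
    if not idx:
        return config.with_points(Y0.copy())
    idx = np.asarray(idx, int)
    U = np.asarray(dirs, float)  # (m, 3)

    zero_dir = np.linalg.norm(U, axis=1) == 0
    A = B[np.ix_(idx, idx)] * (U @ U.T)
    b = np.einsum("mk,mk->m", (B @ Y0)[idx], U)
    ridge = 1e-10 * (np.trace(A) / len(A) + 1.0)
    A[np.diag_indices_from(A)] += ridge
    t = np.linalg.solve(A, -b)
    t[zero_dir] = 0.0

    be0 = float(np.einsum("id,ij,jd->", Y0, B, Y0))
    curve_paths = [np.asarray(p, int) for p in template.curves]
    surf_idx = template.surface_indices

    def apply(tvec):
        Y = Y0.copy()
        np.add.at(Y, idx, tvec[:, None] * U)
        # re-project curve semilandmarks onto the pre-slide polyline
        for path in curve_paths:
            poly = Y0[path]
            Y[path[1:-1]] = _closest_point_on_polyline(poly, Y[path[1:-1]])
        if specimen_mesh is not None and specimen_mesh.n_faces > 0 and len(surf_idx):
            Y[surf_idx] = closest_point_on_mesh(specimen_mesh, Y[surf_idx])[0]
        return Y

    Y = apply(t)
    be = float(np.einsum("id,ij,jd->", Y, B, Y))
    n_halve = 0
    while be > be0 + 1e-12 * max(abs(be0), 1.0) and n_halve < 20:
        t = t / 2.0
        Y = apply(t)
        be = float(np.einsum("id,ij,jd->", Y, B, Y))
        n_halve += 1
    if be > be0 + 1e-12 * max(abs(be0), 1.0):
        Y = Y0.copy()
    return config.with_points(Y)


def _total_be(configs, B) -> float:
    return float(sum(np.einsum("id,ij,jd->", c.points, B, c.points) for c in configs))


def relax_to_template(
    configs,
    template: TemplateDefinition,
    n_iter: int = 5,
    meshes=None,
) -> SlidingResult:
    """Slide every specimen against the template for *n_iter* rounds."""
    if n_iter < 0:
        raise ValueError("n_iter must be non-negative")
    configs = list(configs)
    meshes = meshes if meshes is not None else [None] * len(configs)
    ref = template.config.points
    B = bending_energy_matrix(ref)
    trace = [_total_be(configs, B)]
    for _ in range(n_iter):
        configs = [
            slide_iteration(c, ref, template, m, bending_matrix=B)
            for c, m in zip(configs, meshes)
        ]
        trace.append(_total_be(configs, B))
    return SlidingResult(configs=configs, bending_energy_trace=trace, iterations_run=n_iter)


def relax_to_consensus(
    configs,
    template: TemplateDefinition,
    n_iter: int = 2,
    meshes=None,
) -> SlidingResult:
    """Slide every specimen against the partial-Procrustes consensus.

    The consensus is recomputed from the current configurations at the
    start of every iteration.  The recorded trace entries are measured
    against each iteration's own consensus.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be non-negative")
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("consensus relaxation needs at least 2 configurations")
    meshes = meshes if meshes is not None else [None] * len(configs)
    trace = None
    for _ in range(n_iter):
        consensus = gpa(configs).consensus
        B = bending_energy_matrix(consensus)
        if trace is None:
            trace = [_total_be(configs, B)]
        configs = [
            slide_iteration(c, consensus, template, m, bending_matrix=B)
            for c, m in zip(configs, meshes)
        ]
        trace.append(_total_be(configs, B))
    if trace is None:
        consensus = gpa(configs).consensus
        trace = [_total_be(configs, bending_energy_matrix(consensus))]
    return SlidingResult(configs=configs, bending_energy_trace=trace, iterations_run=n_iter)
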