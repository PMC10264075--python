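"""Landmark and mesh input/output.

Landmark configurations travel in two plain-text dialects:

* the classic morphometrics "TPS" text format (``LM3=`` blocks, one per
  specimen), which carries coordinates only, and
* a flat CSV table (``specimen_id, point_index, x, y, z, class, group``)
  as exported by interactive landmarking software.

Point *class* distinguishes fixed anatomical landmarks from sliding
semilandmarks on curves and surfaces; *group* keys semilandmarks to the
curve or surface patch they slide on.  Dialects that carry no class
metadata (TPS) take it from a template descriptor at read time.

Meshes are triangulated surfaces read and written through :mod:`trimesh`
(PLY / OBJ / STL).  Units are opaque throughout: coordinates are used as
given and never converted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger("osteomorph")

#: Recognised skeletal elements.  Fragment elements are template index
#: subsets of the corresponding complete element.
ELEMENTS = ("complete_femur", "proximal_femur", "distal_femur", "complete_tibia")
SIDES = ("left", "right")
POINT_CLASSES = ("anatomical", "curve_semi", "surface_semi")


class LandmarkParseError(ValueError):
    """Malformed landmark file; message names the offending line."""


class DimensionError(ValueError):
    """Point count disagrees with the template or between specimens."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D landmark configuration.

    Point order is the homology map: point ``i`` corresponds to point
    ``i`` in every other specimen of the same element type.

    Parameters
    ----------
    specimen_id : str
    element : str
        One of :data:`ELEMENTS`.
    side : str
        ``"left"`` or ``"right"``.
    points : (p, 3) float array
    classes : (p,) str array
        Per-point class from :data:`POINT_CLASSES`.
    group : (p,) int array
        Curve id for curve semilandmarks, patch id for surface
        semilandmarks, ``-1`` for anatomical landmarks.
    """

    specimen_id: str
    element: str
    side: str
    points: np.ndarray
    classes: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise DimensionError(
                f"{self.specimen_id}: points must be (p, 3), got {self.points.shape}"
            )
        p = len(self.points)
        self.classes = np.asarray(self.classes)
        self.group = np.asarray(self.group, dtype=int)
        if len(self.classes) != p or len(self.group) != p:
            raise DimensionError(
                f"{self.specimen_id}: points ({p}), classes ({len(self.classes)}) "
                f"and group ({len(self.group)}) lengths differ"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        bad = set(np.unique(self.classes)) - set(POINT_CLASSES)
        if bad:
            raise ValueError(f"{self.specimen_id}: unknown point classes {sorted(bad)}")
        if self.element not in ELEMENTS:
            raise ValueError(f"{self.specimen_id}: unknown element {self.element!r}")
        if self.side not in SIDES:
            raise ValueError(f"{self.specimen_id}: unknown side {self.side!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def mask(self, cls: str) -> np.ndarray:
        """Boolean mask of points of class *cls*."""
        return self.classes == cls

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.classes == c)) for c in POINT_CLASSES}

    def with_points(self, points: np.ndarray, specimen_id: str | None = None) -> "LandmarkConfiguration":
        """Copy carrying new coordinates (metadata shared)."""
        return LandmarkConfiguration(
            specimen_id=specimen_id or self.specimen_id,
            element=self.element,
            side=self.side,
            points=np.asarray(points, dtype=float).copy(),
            classes=self.classes,
            group=self.group,
        )

    def mirrored(self) -> "LandmarkConfiguration":
        """Reflect across the sagittal (y–z) plane, turning a right-side
        element into left form (or back).  Point order is unchanged."""
        pts = self.points.copy()
        pts[:, 0] *= -1.0
        out = self.with_points(pts)
        out.side = "left" if self.side == "right" else "right"
        return out


@dataclass
class Mesh:
    """Triangulated surface: (n, 3) float vertices, (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def drop_degenerate_faces(self, rel_tol: float = 1e-12) -> "Mesh":
        """Remove zero-area triangles (relative to the largest face)."""
        if not len(self.faces):
            return self
        areas = self.face_areas()
        keep = areas > rel_tol * max(areas.max(), np.finfo(float).tiny)
        if keep.all():
            return self
        return Mesh(self.vertices, self.faces[keep])

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length where defined)."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area-weighted
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, f[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm


# ---------------------------------------------------------------------------
# landmark dialects
# ---------------------------------------------------------------------------

def _apply_template_metadata(configs, template_descriptor):
    """Fill classes/group from a template descriptor dict (keys
    ``classes`` and ``group`` as lists)."""
    classes = np.asarray(template_descriptor["classes"])
    group = np.asarray(template_descriptor["group"], dtype=int)
    out = []
    for c in configs:
        if c.n_points != len(classes):
            raise DimensionError(
                f"{c.specimen_id}: {c.n_points} points but template descriptor has {len(classes)}"
            )
        out.append(
            LandmarkConfiguration(c.specimen_id, c.element, c.side, c.points, classes, group)
        )
    return out


def read_landmarks(
    path,
    dialect: str = "tps_text",
    element: str = "complete_femur",
    side: str = "left",
    template_descriptor: dict | None = None,
) -> list[LandmarkConfiguration]:
    """Read landmark configurations from *path*.

    For the ``tps_text`` dialect (which carries no class metadata) the
    per-point classes and grouping come from *template_descriptor*; when
    none is given all points are marked anatomical.  The ``table``
    dialect reads class/group from its own columns when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tps_text":
        configs = _read_tps_text(path, element, side)
    elif dialect == "table":
        configs = _read_table(path, element, side)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")
    if not configs:
        warnings.warn(f"{path}: no landmark records found", stacklevel=2)
    if template_descriptor is not None:
        configs = _apply_template_metadata(configs, template_descriptor)
    return configs


def _read_tps_text(path: Path, element: str, side: str) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text().splitlines()
    i, n_anon = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise LandmarkParseError(f"{path}:{i + 1}: expected 'LM3=', got {line!r}")
        try:
            p = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise LandmarkParseError(f"{path}:{i + 1}: bad landmark count {line!r}") from exc
        pts = np.empty((p, 3))
        for j in range(p):
            row = lines[i + 1 + j].split()
            if len(row) != 3:
                raise LandmarkParseError(
                    f"{path}:{i + 2 + j}: expected 3 coordinates, got {len(row)}"
                )
            try:
                pts[j] = [float(x) for x in row]
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{i + 2 + j}: non-numeric coordinate") from exc
        i += 1 + p
        spec_id = None
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            if line.upper().startswith("LM3="):
                break
            if line.upper().startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            i += 1  # ID=, IMAGE=, SCALE= and friends
        if spec_id is None:
            n_anon += 1
            spec_id = f"specimen_{n_anon}"
        configs.append(
            LandmarkConfiguration(
                spec_id, element, side, pts,
                np.full(p, "anatomical"), np.full(p, -1, dtype=int),
            )
        )
    return configs


def write_landmarks(configs: Sequence[LandmarkConfiguration], path, dialect: str = "tps_text") -> None:
    path = Path(path)
    if dialect == "tps_text":
        with path.open("w") as fh:
            for c in configs:
                fh.write(f"LM3={c.n_points}\n")
                for x, y, z in c.points:
                    fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
                fh.write(f"ID={c.specimen_id}\n")
    elif dialect == "table":
        frames = []
        for c in configs:
            frames.append(
                pd.DataFrame(
                    {
                        "specimen_id": c.specimen_id,
                        "point_index": np.arange(c.n_points),
                        "x": c.points[:, 0],
                        "y": c.points[:, 1],
                        "z": c.points[:, 2],
                        "class": c.classes,
                        "group": c.group,
                        "element": c.element,
                        "side": c.side,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


def _read_table(path: Path, element: str, side: str) -> list[LandmarkConfiguration]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    required = {"specimen_id", "point_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkParseError(f"{path}: missing columns {sorted(missing)}")
    configs = []
    for spec_id, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("point_index")
        p = len(sub)
        classes = (
            sub["class"].to_numpy() if "class" in sub else np.full(p, "anatomical")
        )
        group = sub["group"].to_numpy() if "group" in sub else np.full(p, -1)
        configs.append(
            LandmarkConfiguration(
                str(spec_id),
                str(sub["element"].iloc[0]) if "element" in sub else element,
                str(sub["side"].iloc[0]) if "side" in sub else side,
                sub[["x", "y", "z"]].to_numpy(dtype=float),
                classes,
                np.asarray(group, dtype=int),
            )
        )
    return configs


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

_MESH_EXTENSIONS = {".ply", ".obj", ".stl"}


def read_mesh(path) -> Mesh:
    """Read a PLY/OBJ/STL surface.

    Vertex order is preserved for PLY and OBJ.  STL stores no shared
    vertices, so vertices are merged by exact coordinate match (face
    count unchanged).  Zero-area faces are dropped on load.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _MESH_EXTENSIONS:
        raise ValueError(f"unknown mesh format {ext!r} (expected PLY/OBJ/STL)")
    tm = trimesh.load(str(path), process=False, force="mesh")
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=int)
    if ext == ".stl":
        vertices, faces = _merge_exact_vertices(vertices, faces)
    return Mesh(vertices, faces).drop_degenerate_faces()


def _merge_exact_vertices(vertices: np.ndarray, faces: np.ndarray):
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def write_mesh(mesh: Mesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise ValueError(f"unknown mesh format {path.suffix!r} (expected PLY/OBJ/STL)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if path.suffix.lower() == ".ply" else {}
    tm.export(str(path), **kwargs)


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_results(bundle: dict, path) -> None:
    """Persist a (possibly numpy-valued) result dictionary as JSON."""
    Path(path).write_text(json.dumps(_jsonify(bundle), indent=1, sort_keys=True))


def load_results(path) -> dict:
    return json.loads(Path(path).read_text())
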