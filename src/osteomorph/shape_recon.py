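"""Mean-shape and per-cluster shape reconstruction with mesh warping.

Visualisation of what a PC axis (or a mixture cluster along it) means
anatomically: reconstruct the landmark configuration at a position in
shape space, then carry the template's triangulated surface onto it with
the interpolating thin-plate spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_core import GPAResult, tps_fit, tps_warp
from .io_formats import Mesh
from .morphostats import GMMResult, PCAResult
from .semilandmarks import TemplateDefinition


@dataclass
class ClusterShapes:
    """Per-cluster mean landmark configurations (p, 3) and, optionally,
    warped meshes, keyed by cluster label."""

    shapes: dict
    meshes: dict
    axis: int


def consensus_mesh(template: TemplateDefinition, gpa_result: GPAResult) -> Mesh:
    """Warp the template mesh onto the Procrustes consensus.

    Fits the TPS template configuration → consensus and evaluates it at
    every template mesh vertex; the warped mesh's landmarks coincide
    with the consensus by interpolation.
    """
    if template.mesh is None:
        raise ValueError("template has no mesh")
    model = tps_fit(template.config.points, gpa_result.consensus)
    return Mesh(tps_warp(model, template.mesh.vertices), template.mesh.faces.copy())


def reconstruct_shape(pca_result: PCAResult, scores_1d, axes=None) -> np.ndarray:
    """Fold a point in score space back to a (p, 3) configuration.

    *scores_1d* holds one score per axis in *axes* (default: leading
    axes); all other axes are held at zero, so reconstruction is linear
    about the consensus.
    """
    scores_1d = np.atleast_1d(np.asarray(scores_1d, float))
    if axes is None:
        axes = list(range(1, len(scores_1d) + 1))
    flat = pca_result.mean_flat.copy()
    for s, ax in zip(scores_1d, axes):
        flat = flat + s * pca_result.loadings[ax - 1]
    return flat.reshape(-1, 3)


def cluster_mean_shapes(
    pca_result: PCAResult,
    gmm: GMMResult,
    axis: int | None = None,
    template: TemplateDefinition | None = None,
    full_space: bool = False,
) -> ClusterShapes:
    """Mean shape of each mixture cluster.

    By default each cluster's mean score *on the dimorphic axis only* is
    folded back to a configuration (other axes at zero); with
    ``full_space=True`` the cluster mean over all retained axes is used.
    When a *template* with a mesh is given, the consensus mesh is warped
    onto each cluster shape.
    """
    axis = axis if axis is not None else gmm.axis
    if gmm.selected_G < 2:
        raise ValueError("cluster shapes need a mixture with at least 2 components")
    shapes, meshes = {}, {}
    for g in range(gmm.selected_G):
        members = gmm.assignments == g
        if not members.any():
            raise ValueError(f"cluster {g} is empty")
        if full_space:
            mean_scores = pca_result.scores[members].mean(axis=0)
            shape = reconstruct_shape(
                pca_result, mean_scores, axes=list(range(1, pca_result.n_components + 1))
            )
        else:
            mean_score = float(pca_result.scores[members, axis - 1].mean())
            shape = reconstruct_shape(pca_result, [mean_score], axes=[axis])
        shapes[g] = shape
        if template is not None and template.mesh is not None:
            model = tps_fit(template.config.points, shape)
            meshes[g] = Mesh(tps_warp(model, template.mesh.vertices), template.mesh.faces.copy())
    return ClusterShapes(shapes=shapes, meshes=meshes, axis=axis)
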