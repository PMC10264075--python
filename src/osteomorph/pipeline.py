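"""Pipeline orchestration: the full study as ordered, resumable stages.

Stages run in the method's order — load or generate, mirror right-side
elements to left form, project template surface patches (when meshes are
available), five sliding iterations against the template, two against
the recomputed Procrustes consensus, generalized Procrustes analysis,
PCA, the per-axis mixture/allometry scan, cluster mean shapes for any
dimorphic axis, and cluster-consistency checks between the
complete-bone analysis and fragment analyses of the same specimens.

Every stage's inputs and outputs are plain CSV/JSON files, so each is
individually invokable (see :mod:`osteomorph.cli`) and real digitised
data can be slotted in at any stage in place of the generator.  All
randomness flows from the config seed; a re-run with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, morphostats, semilandmarks, shape_recon, synthetic_data
from .geometry_core import GPAResult, gpa
from .io_formats import LandmarkConfiguration, save_results
from .morphostats import (cluster_consistency, dimorphism_scan, label_accuracy, pca)
from .semilandmarks import TemplateDefinition, relax_to_consensus, relax_to_template
from .synthetic_data import PopulationSpec, build_ideal_femur, extract_fragment

logger = logging.getLogger("osteomorph")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serialised into the report."""

    population: PopulationSpec | None = None
    input_landmarks: str | None = None
    input_dialect: str = "table"
    element: str = "complete_femur"
    mirror: bool = True
    relax_template_iters: int = 5
    relax_consensus_iters: int = 2
    g_max: int = 9
    allometry_alpha: float = 0.05
    axes: list | None = None
    fragments: tuple = ("distal",)
    fragment_counts: dict | None = None  # portion -> (anat, curve, surface); None = census
    skip_sliding: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.population is None and self.input_landmarks is None:
            raise ValueError("config needs either a population spec or an input path")
        if self.relax_template_iters < 0 or self.relax_consensus_iters < 0:
            raise ValueError("relaxation iteration counts must be non-negative")
        if self.g_max < 1:
            raise ValueError("g_max must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file; the ``population``
        key, if present, holds :class:`PopulationSpec` fields."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        pop = data.pop("population", None)
        cfg = cls(**data)
        if pop is not None:
            cfg.population = PopulationSpec(**pop)
        if cfg.fragments is not None:
            cfg.fragments = tuple(cfg.fragments)
        return cfg


def _analysis_block(configs, axes, g_max, alpha, seed):
    """GPA → PCA → dimorphism scan for one element analysis."""
    g = gpa(configs)
    p = pca(g)
    scan = dimorphism_scan(p, g, axes=axes, G_max=g_max, allometry_alpha=alpha, seed=seed)
    return g, p, scan


def _scan_summary(p, scan):
    flagged = sorted(ax for ax, s in scan.items() if s.flagged)
    return {
        "variance_fraction": p.variance_fraction[: max(5, len(scan))].tolist(),
        "axes": {
            str(ax): {
                "selected_G": s.gmm.selected_G,
                "selected_model": s.gmm.selected_model,
                "mixing_proportions": s.gmm.mixing_proportions.tolist(),
                "allometry_r": s.allometry.r,
                "allometry_p": s.allometry.p_value,
                "flagged": s.flagged,
            }
            for ax, s in scan.items()
        },
        "flagged_axes": flagged,
    }


def run_pipeline(config: RunConfig, outdir=None, template: TemplateDefinition | None = None) -> dict:
    """Execute the full pipeline and return the report dictionary.

    When *outdir* is given, stage intermediates (landmark tables, scores,
    BIC tables, assignments) and the JSON report are persisted there.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": []}

    # --- stage: load or generate -------------------------------------
    truth = None
    meshes = None
    if config.population is not None:
        if template is None:
            template = build_ideal_femur(element=config.element)
        specimens = synthetic_data.generate_population(config.population, template)
        configs = [s.config for s in specimens]
        if config.population.with_meshes:
            meshes = [s.mesh for s in specimens]
        truth = {s.config.specimen_id: s.truth for s in specimens}
    else:
        configs = io_formats.read_landmarks(
            config.input_landmarks,
            dialect=config.input_dialect,
            element=config.element,
            template_descriptor=template.to_descriptor() if template else None,
        )
        specimens = None
    report["stages"].append({"name": "load", "n_specimens": len(configs)})
    logger.info("loaded %d specimens", len(configs))

    # --- stage: mirror right-side elements ---------------------------
    if config.mirror:
        n_mirrored = sum(c.side == "right" for c in configs)
        configs = [c.mirrored() if c.side == "right" else c for c in configs]
        report["stages"].append({"name": "mirror", "n_mirrored": n_mirrored})

    # --- stage: patch projection (meshes required) -------------------
    if meshes is not None and template is not None and not config.skip_sliding:
        fixed_idx = template.fixed_indices
        projected = []
        for c, m in zip(configs, meshes):
            fixed = LandmarkConfiguration(
                c.specimen_id, c.element, c.side, c.points[fixed_idx],
                c.classes[fixed_idx], c.group[fixed_idx],
            )
            projected.append(semilandmarks.project_patch(template, m, fixed))
        configs = projected
        report["stages"].append({"name": "project_patch", "n_specimens": len(configs)})

    # --- stages: sliding relaxation ----------------------------------
    if not config.skip_sliding and template is not None:
        rt = relax_to_template(configs, template, n_iter=config.relax_template_iters,
                               meshes=meshes)
        configs = rt.configs
        report["stages"].append(
            {"name": "relax_to_template", "bending_energy_trace": rt.bending_energy_trace}
        )
        rc = relax_to_consensus(configs, template, n_iter=config.relax_consensus_iters,
                                meshes=meshes)
        configs = rc.configs
        report["stages"].append(
            {"name": "relax_to_consensus", "bending_energy_trace": rc.bending_energy_trace}
        )
        if out is not None:
            io_formats.write_landmarks(configs, out / "relaxed_landmarks.csv", dialect="table")

    # --- stages: superimposition, ordination, scan -------------------
    g, p, scan = _analysis_block(configs, config.axes, config.g_max,
                                 config.allometry_alpha, config.seed)
    report["stages"].append({"name": "gpa", "iterations": g.iterations, "converged": g.converged})
    report["complete"] = _scan_summary(p, scan)
    flagged = report["complete"]["flagged_axes"]

    assignments_complete = {}
    if flagged:
        ax = flagged[0]
        assignments_complete = dict(zip(p.specimen_ids, scan[ax].gmm.assignments.tolist()))
        shapes = shape_recon.cluster_mean_shapes(p, scan[ax].gmm, axis=ax, template=template)
        report["cluster_shapes"] = {
            str(k): {"n_points": len(v)} for k, v in shapes.shapes.items()
        }
        if out is not None and shapes.meshes:
            for k, m in shapes.meshes.items():
                io_formats.write_mesh(m, out / f"cluster_{k}_mean_shape.ply")

    # --- stage: fragment analyses + consistency ----------------------
    report["fragments"] = {}
    if config.element == "complete_femur" and config.fragments and template is not None:
        for portion in config.fragments:
            counts = (config.fragment_counts or {}).get(portion)
            frags = [extract_fragment(c, portion, template, counts=counts) for c in configs]
            gf, pf, scanf = _analysis_block(frags, config.axes, config.g_max,
                                            config.allometry_alpha, config.seed)
            block = _scan_summary(pf, scanf)
            f_flagged = block["flagged_axes"]
            if f_flagged and assignments_complete:
                axf = f_flagged[0]
                assign_f = dict(zip(pf.specimen_ids, scanf[axf].gmm.assignments.tolist()))
                block["consistency_with_complete"] = cluster_consistency(
                    assignments_complete, assign_f
                )
            report["fragments"][portion] = block

    # --- optional truth-based evaluation (synthetic runs only) -------
    if truth is not None and flagged:
        ax = flagged[0]
        t = np.array([truth[sid]["morph"] for sid in p.specimen_ids])
        report["truth_eval"] = {
            "label_accuracy": label_accuracy(scan[ax].gmm.assignments, t),
            "axis": ax,
        }

    if out is not None:
        pd.DataFrame(
            {"specimen_id": p.specimen_ids,
             **{f"PC{j+1}": p.scores[:, j] for j in range(min(10, p.n_components))},
             "log_centroid_size": g.log_centroid_sizes}
        ).to_csv(out / "scores.csv", index=False)
        rows = []
        for ax, s in scan.items():
            for (variant, G), bic in s.gmm.bic_table.items():
                rows.append({"axis": ax, "variant": variant, "G": G, "BIC": bic})
        pd.DataFrame(rows).to_csv(out / "bic_table.csv", index=False)
        if assignments_complete:
            pd.DataFrame(
                sorted(assignments_complete.items()), columns=["specimen_id", "cluster"]
            ).to_csv(out / "assignments.csv", index=False)
        save_results(report, out / "report.json")
    return report
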