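"""Orchestration: simulate/read -> filter -> annotate -> PCA / zones / stats.

One :class:`RunConfig` drives a whole run; stages execute in the standard
post-processing order (filter cascade, then annotation, then scaling and
ordination / comparison), every output lands as a CSV in the run directory,
and a ``manifest.json`` records the config hash, the seed and per-stage row
counts.  Re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from . import comparison, multivariate, preprocess
from .annotation import AnnotationConfig, annotate_table
from .chem_mass import DEFAULT_NEGATIVE_ADDUCTS
from .feature_io import (
    load_reference_compounds,
    read_compound_db,
    read_feature_table,
    write_annotation_table,
    write_feature_table,
)
from .preprocess import FilterConfig
from .synthetic_data import SimConfig, generate

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulate=True`` (inputs come from the seeded generator) or
    ``features_path``/``metadata_path`` point at CSV inputs.  ``analyses``
    selects optional downstream stages out of ``annotate``, ``pca``,
    ``zones`` and ``stats``.
    """

    seed: int = 0
    simulate: bool = True
    sim: Optional[SimConfig] = None
    features_path: Optional[str] = None
    metadata_path: Optional[str] = None
    compounds_path: Optional[str] = None  # None -> packaged reference database
    filters: FilterConfig = field(default_factory=FilterConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    analyses: Tuple[str, ...] = ("annotate",)
    scale_by_area: bool = False
    pca_components: int = 2
    zone_condition_a: Optional[str] = None
    zone_condition_b: Optional[str] = None
    zone_exclude_condition: Optional[str] = None

    def __post_init__(self) -> None:
        known = {"annotate", "pca", "zones", "stats"}
        unknown = set(self.analyses) - known
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if not self.simulate and not (self.features_path and self.metadata_path):
            raise ValueError("without simulation, features_path and metadata_path are required")

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            sim = dataclasses.asdict(self.sim)
            if self.sim.compounds is not None:
                sim["compounds"] = [
                    {"name": c.name, "formula": c.formula_str, "source": c.source}
                    for c in self.sim.compounds
                ]
            sim["adducts"] = [a.name for a in self.sim.adducts]
            d["sim"] = sim
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _effective_sim(cfg: RunConfig) -> SimConfig:
    sim = cfg.sim if cfg.sim is not None else SimConfig()
    return dataclasses.replace(sim, seed=cfg.seed)


def run_pipeline(cfg: RunConfig, outdir) -> Dict:
    """Execute the configured stages; returns the manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    def record(stage: str, rows: int) -> None:
        manifest["stages"][stage] = int(rows)
        log.info("stage %s: %d rows", stage, rows)

    # ---- input --------------------------------------------------------
    try:
        if cfg.simulate:
            table, truth = generate(_effective_sim(cfg))
            write_feature_table(table, outdir / "features.csv", outdir / "metadata.csv")
            truth.to_csv(outdir / "truth.csv")
            record("simulate", table.n_features)
        else:
            table = read_feature_table(cfg.features_path, cfg.metadata_path)
            record("input", table.n_features)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc

    # ---- filter cascade ----------------------------------------------
    try:
        filtered, counts = preprocess.apply_filter_cascade(table, cfg.filters)
        for name, n in counts.items():
            if name != "input":
                record(f"filter_{name}", n)
        write_feature_table(filtered, outdir / "filtered_features.csv", outdir / "filtered_metadata.csv")
    except Exception as exc:
        raise PipelineError(f"stage preprocess: {exc}") from exc

    # ---- annotation ---------------------------------------------------
    if "annotate" in cfg.analyses:
        try:
            db = (
                read_compound_db(cfg.compounds_path)
                if cfg.compounds_path
                else load_reference_compounds()
            )
            annotations = annotate_table(filtered, db, DEFAULT_NEGATIVE_ADDUCTS, cfg.annotation)
            write_annotation_table(annotations, outdir / "annotations.csv")
            record("annotate", len(annotations))
        except Exception as exc:
            raise PipelineError(f"stage annotate: {exc}") from exc

    # ---- PCA ----------------------------------------------------------
    if "pca" in cfg.analyses:
        try:
            working = preprocess.scale_by_surface_area(filtered) if cfg.scale_by_area else filtered
            sample_ids = working.sample_ids()
            matrix = working.intensities[sample_ids].T  # samples x features
            scaled, _ = multivariate.unit_variance_scale(matrix)
            k = min(cfg.pca_components, len(sample_ids) - 1, matrix.shape[1])
            result = multivariate.pca_svd(scaled, k)
            scores = pd.DataFrame(
                result.scores, index=sample_ids, columns=[f"PC{i+1}" for i in range(k)]
            )
            scores["condition"] = working.samples.loc[sample_ids, "condition"].to_numpy()
            scores.rename_axis("sample_id").to_csv(outdir / "scores.csv")
            pd.DataFrame(
                result.loadings,
                index=matrix.columns,
                columns=[f"PC{i+1}" for i in range(k)],
            ).rename_axis("feature_id").to_csv(outdir / "loadings.csv")
            pd.DataFrame(
                {"component": [f"PC{i+1}" for i in range(k)],
                 "variance_explained": result.variance_explained}
            ).to_csv(outdir / "variance.csv", index=False)
            if k >= 2:
                ellipse_rows = []
                for condition in working.conditions:
                    pts = scores.loc[scores["condition"] == condition, ["PC1", "PC2"]].to_numpy()
                    if len(pts) < 3:
                        continue
                    e = multivariate.confidence_ellipse(pts)
                    ellipse_rows.append(
                        {
                            "condition": condition,
                            "center_x": e.center[0],
                            "center_y": e.center[1],
                            "semi_major": e.semi_axes[0],
                            "semi_minor": e.semi_axes[1],
                            "angle_rad": e.angle_rad,
                            "degenerate": e.degenerate,
                        }
                    )
                pd.DataFrame(ellipse_rows).to_csv(outdir / "ellipses.csv", index=False)
            record("pca", len(scores))
        except Exception as exc:
            raise PipelineError(f"stage pca: {exc}") from exc

    # ---- zones --------------------------------------------------------
    if "zones" in cfg.analyses:
        try:
            cond_a, cond_b = cfg.zone_condition_a, cfg.zone_condition_b
            if cond_a is None or cond_b is None:
                conds = filtered.conditions
                if len(conds) < 2:
                    raise ValueError("zone classification needs two conditions")
                cond_a, cond_b = conds[0], conds[1]
            zones = comparison.classify_zones(
                filtered, cond_a, cond_b, cfg.filters,
                exclude_condition=cfg.zone_exclude_condition,
            )
            zones.rename_axis("feature_id").to_csv(outdir / "zones.csv")
            record("zones", len(zones))
        except Exception as exc:
            raise PipelineError(f"stage zones: {exc}") from exc

    # ---- per-feature statistics ---------------------------------------
    if "stats" in cfg.analyses:
        try:
            rows = []
            for fid in filtered.features.index:
                res = comparison.feature_group_test(filtered, fid, cfg.filters)
                rows.append({"feature_id": fid, "H": res["H"], "p_value": res["p_value"]})
            pd.DataFrame(rows).to_csv(outdir / "stats.csv", index=False)
            record("stats", len(rows))
        except Exception as exc:
            raise PipelineError(f"stage stats: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
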