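"""Seeded simulator of aligned LC-MS feature tables with known ground truth.

The generator emulates what the alignment software hands to this pipeline,
for a microscale culture study: each database compound ionises into one or
more negative-mode adducts, all sharing a retention-time anchor (with jitter
bounded by the adduct-grouping window), with observed m/z perturbed by
ppm-scale multiplicative mass noise.  Intensities are log-normal with
per-condition extraction multipliers (e.g. per-solvent efficiencies),
per-replicate noise and random dropout; contaminant features live in the
solvent blanks (and, optionally, in every sample).  Every feature is tied to
its hidden (compound, adduct, condition-presence) truth so that annotation,
presence calls and zone classification can be scored exactly.

What it does *not* emulate: isotope envelopes, chimeric features, RT drift
between samples, and correlated (batch) intensity structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation
from .chem_mass import (
    AdductSpec,
    DEFAULT_NEGATIVE_ADDUCTS,
    adduct_mz,
    monoisotopic_mass,
)
from .feature_io import CompoundRecord, FeatureTable, load_reference_compounds

__all__ = [
    "SimConfig",
    "generate",
    "RecoveryScore",
    "score_annotations",
    "score_presence",
    "score_zones",
]

#: Surface area of the standard 3.5-mm culture well, mm2.
_STANDARD_WELL_AREA = math.pi * (3.5 / 2.0) ** 2


@dataclass(frozen=True)
class SimConfig:
    """Study design and noise model for one simulated experiment.

    Defaults mirror the microscale solvent-comparison design: the curated
    19-compound database, three extraction conditions with five replicates
    each, 2-ppm mass noise (truncated at the 10-ppm annotation gate), adduct
    RT jitter within the 45-s grouping window, log-normal intensities around
    1e5 a.u., 10% replicate dropout and a handful of blank-borne contaminants
    on a 0-3,000-s gradient.
    """

    compounds: Optional[Tuple[CompoundRecord, ...]] = None  # None -> curated reference db
    conditions: Tuple[str, ...] = ("chloroform", "pentanol", "caprolactone")
    replicates: int = 5
    #: condition -> compound-name -> abundance multiplier; None -> drawn
    #: log-normally with ``condition_effect_sigma``.  A multiplier of 0 makes
    #: the compound absent from that condition.
    condition_multipliers: Optional[Mapping[str, Mapping[str, float]]] = None
    condition_effect_sigma: float = 1.0
    mass_noise_ppm: float = 2.0
    mass_noise_max_ppm: float = 10.0
    rt_jitter_s: float = 45.0
    rt_min_s: float = 60.0
    rt_max_s: float = 2940.0
    base_intensity_log_mu: float = math.log(1e5)
    base_intensity_log_sigma: float = 1.0
    adduct_intensity_log_mu: float = -1.0
    adduct_intensity_log_sigma: float = 0.5
    replicate_log_sigma: float = 0.3
    dropout_p: float = 0.10
    extra_adduct_p: float = 0.5
    n_contaminants: int = 5
    contaminant_in_samples: bool = True
    n_blanks: int = 3
    detection_floor: float = 0.0
    surface_area_mm2: float = _STANDARD_WELL_AREA
    adducts: Tuple[AdductSpec, ...] = tuple(DEFAULT_NEGATIVE_ADDUCTS)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_p", "extra_adduct_p"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mass_noise_ppm < 0:
            raise ValueError("mass_noise_ppm must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")

    def resolved_compounds(self) -> Tuple[CompoundRecord, ...]:
        if self.compounds is not None:
            return tuple(self.compounds)
        return tuple(load_reference_compounds())


def _truncated_normal(rng: np.random.Generator, sigma: float, bound: float, size: int) -> np.ndarray:
    """Normal(0, sigma) truncated to (-bound, bound) by redrawing."""
    if sigma == 0.0:
        return np.zeros(size)
    out = rng.normal(0.0, sigma, size)
    bad = np.abs(out) >= bound
    while bad.any():
        out[bad] = rng.normal(0.0, sigma, int(bad.sum()))
        bad = np.abs(out) >= bound
    return out


def generate(cfg: SimConfig) -> Tuple[FeatureTable, pd.DataFrame]:
    """Simulate one experiment; returns the feature table and its ground truth.

    The ground truth is a DataFrame indexed by feature_id with columns
    ``compound``, ``adduct``, ``true_mz``, ``rt_anchor_s``, ``is_contaminant``
    and one boolean ``present_<condition>`` column per condition.  Identical
    configs (including the seed) give identical output.
    """
    compounds = cfg.resolved_compounds()
    if not compounds and cfg.n_contaminants == 0:
        raise ValueError("empty compound list with zero contaminants")
    rng = np.random.default_rng(cfg.seed)

    # sample metadata
    meta_rows = []
    for condition in cfg.conditions:
        for rep in range(1, cfg.replicates + 1):
            meta_rows.append(
                {
                    "sample_id": f"{condition}_r{rep}",
                    "condition": condition,
                    "replicate": rep,
                    "is_blank": False,
                    "surface_area_mm2": cfg.surface_area_mm2,
                }
            )
    for rep in range(1, cfg.n_blanks + 1):
        meta_rows.append(
            {
                "sample_id": f"blank_r{rep}",
                "condition": "solvent-blank",
                "replicate": rep,
                "is_blank": True,
                "surface_area_mm2": cfg.surface_area_mm2,
            }
        )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    sample_ids = list(samples.index)

    # per-condition abundance multipliers
    multipliers: Dict[str, Dict[str, float]] = {}
    for condition in cfg.conditions:
        if cfg.condition_multipliers is not None:
            given = cfg.condition_multipliers.get(condition, {})
            multipliers[condition] = {rec.name: float(given.get(rec.name, 1.0)) for rec in compounds}
        else:
            multipliers[condition] = {
                rec.name: float(np.exp(rng.normal(0.0, cfg.condition_effect_sigma)))
                for rec in compounds
            }

    primary = cfg.adducts[0] if cfg.adducts else None
    feat_rows: List[dict] = []
    truth_rows: List[dict] = []
    intensity_rows: List[np.ndarray] = []
    fid = 0
    for rec in compounds:
        neutral = monoisotopic_mass(rec.formula)
        chosen = [primary] + [
            spec for spec in cfg.adducts[1:] if rng.random() < cfg.extra_adduct_p
        ]
        anchor = rng.uniform(cfg.rt_min_s, cfg.rt_max_s)
        base = float(np.exp(rng.normal(cfg.base_intensity_log_mu, cfg.base_intensity_log_sigma)))
        for spec in chosen:
            fid += 1
            feature_id = f"F{fid:03d}"
            true_mz = adduct_mz(neutral, spec)
            eps_ppm = float(
                _truncated_normal(rng, cfg.mass_noise_ppm, cfg.mass_noise_max_ppm, 1)[0]
            )
            observed_mz = true_mz * (1.0 + 1e-6 * eps_ppm)
            rt = anchor + rng.uniform(-cfg.rt_jitter_s / 2.0, cfg.rt_jitter_s / 2.0)
            rt = float(np.clip(rt, 0.0, None))
            factor = 1.0 if spec is primary else float(
                np.exp(rng.normal(cfg.adduct_intensity_log_mu, cfg.adduct_intensity_log_sigma))
            )
            row = np.zeros(len(sample_ids))
            for si, sid in enumerate(sample_ids):
                if samples.loc[sid, "is_blank"]:
                    continue
                condition = samples.loc[sid, "condition"]
                mult = multipliers[condition][rec.name]
                if mult <= 0.0:
                    continue
                noise = float(np.exp(rng.normal(0.0, cfg.replicate_log_sigma)))
                value = base * factor * mult * noise
                if rng.random() < cfg.dropout_p or value <= cfg.detection_floor:
                    value = 0.0
                row[si] = value
            feat_rows.append(
                {
                    "feature_id": feature_id,
                    "mz": observed_mz,
                    "rt_s": rt,
                    "q_value": float(rng.uniform(0.001, 0.049)),
                }
            )
            truth = {
                "feature_id": feature_id,
                "compound": rec.name,
                "adduct": spec.name,
                "true_mz": true_mz,
                "rt_anchor_s": anchor,
                "is_contaminant": False,
            }
            for condition in cfg.conditions:
                truth[f"present_{condition}"] = multipliers[condition][rec.name] > 0.0
            truth_rows.append(truth)
            intensity_rows.append(row)

    for c in range(1, cfg.n_contaminants + 1):
        fid += 1
        feature_id = f"C{c:02d}"
        mz = float(rng.uniform(120.0, 900.0))
        rt = float(rng.uniform(cfg.rt_min_s, cfg.rt_max_s))
        level = float(np.exp(rng.normal(cfg.base_intensity_log_mu, cfg.base_intensity_log_sigma)))
        row = np.zeros(len(sample_ids))
        for si, sid in enumerate(sample_ids):
            is_blank = bool(samples.loc[sid, "is_blank"])
            if not is_blank and not cfg.contaminant_in_samples:
                continue
            noise = float(np.exp(rng.normal(0.0, cfg.replicate_log_sigma)))
            row[si] = level * noise
        feat_rows.append(
            {
                "feature_id": feature_id,
                "mz": mz,
                "rt_s": rt,
                "q_value": float(rng.uniform(0.001, 0.049)),
            }
        )
        truth = {
            "feature_id": feature_id,
            "compound": "",
            "adduct": "",
            "true_mz": mz,
            "rt_anchor_s": rt,
            "is_contaminant": True,
        }
        for condition in cfg.conditions:
            truth[f"present_{condition}"] = bool(cfg.contaminant_in_samples)
        truth_rows.append(truth)
        intensity_rows.append(row)

    features = pd.DataFrame(feat_rows).set_index("feature_id")
    intensities = pd.DataFrame(
        np.vstack(intensity_rows) if intensity_rows else np.zeros((0, len(sample_ids))),
        index=features.index,
        columns=sample_ids,
    )
    truth_df = pd.DataFrame(truth_rows).set_index("feature_id")
    table = FeatureTable(features, intensities, samples)
    return table, truth_df


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryScore:
    """Precision/recall against simulator ground truth.

    With an empty prediction set, precision is 1.0 by convention and
    ``empty_prediction`` is flagged.
    """

    precision: float
    recall: float
    n_true: int
    n_predicted: int
    empty_prediction: bool = False


def _score_sets(predicted: Set, true: Set) -> RecoveryScore:
    if not predicted:
        if true:
            warnings.warn("empty prediction set: precision = 1.0 by convention")
        return RecoveryScore(
            precision=1.0,
            recall=0.0 if true else 1.0,
            n_true=len(true),
            n_predicted=0,
            empty_prediction=True,
        )
    tp = len(predicted & true)
    return RecoveryScore(
        precision=tp / len(predicted),
        recall=tp / len(true) if true else 1.0,
        n_true=len(true),
        n_predicted=len(predicted),
    )


def score_annotations(
    annotations: Sequence[Annotation], truth: pd.DataFrame, level: str = "feature"
) -> RecoveryScore:
    """Score final annotations against truth.

    ``level="feature"`` compares (feature_id, compound, adduct) triples over
    non-contaminant features; ``level="compound"`` compares the recovered
    compound sets.
    """
    real = truth[~truth["is_contaminant"]]
    if level == "feature":
        true_set = set(zip(real.index, real["compound"], real["adduct"]))
        pred_set = {(a.feature_id, a.compound, a.adduct) for a in annotations}
    elif level == "compound":
        true_set = set(real["compound"])
        pred_set = {a.compound for a in annotations}
    else:
        raise ValueError(f"unknown level {level!r}")
    return _score_sets(pred_set, true_set)


def score_presence(calls: pd.Series, truth: pd.DataFrame, condition: str) -> RecoveryScore:
    """Score a boolean presence call against the designed presence pattern.

    Only non-contaminant features in the calls' index are scored (the
    prediction may be over a filtered table).
    """
    col = f"present_{condition}"
    if col not in truth.columns:
        raise ValueError(f"ground truth has no presence column for condition {condition!r}")
    ids = [fid for fid in calls.index if fid in truth.index and not truth.loc[fid, "is_contaminant"]]
    if len(ids) != len(calls.index):
        missing = set(calls.index) - set(truth.index)
        if missing:
            raise ValueError(f"features missing from ground truth: {sorted(missing)[:5]}")
    pred_set = {fid for fid in ids if calls[fid]}
    true_set = {fid for fid in ids if truth.loc[fid, col]}
    return _score_sets(pred_set, true_set)


def score_zones(
    zones: pd.DataFrame, truth: pd.DataFrame, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Confusion summary of predicted vs designed zones for two conditions.

    Returns one row per (true_zone, predicted_zone) pair with its feature
    count; perfect recovery puts all mass on the diagonal.
    """
    rows = []
    for fid in zones.index:
        if fid not in truth.index or truth.loc[fid, "is_contaminant"]:
            continue
        ta = bool(truth.loc[fid, f"present_{condition_a}"])
        tb = bool(truth.loc[fid, f"present_{condition_b}"])
        true_zone = "shared" if (ta and tb) else "A-only" if ta else "B-only" if tb else "neither"
        rows.append({"true_zone": true_zone, "predicted_zone": zones.loc[fid, "zone"]})
    if not rows:
        return pd.DataFrame(columns=["true_zone", "predicted_zone", "count"])
    df = pd.DataFrame(rows)
    return df.value_counts(["true_zone", "predicted_zone"]).rename("count").reset_index()
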