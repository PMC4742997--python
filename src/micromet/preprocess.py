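"""Feature-filtering cascade and surface-area normalisation.

The cascade mirrors the standard post-alignment cleanup for untargeted
microbial metabolomics: drop features by q-value, require detection in at
least 66% of the replicates of some condition, remove anything seen in a
solvent blank, and drop low-maximum-intensity features.  Filters only ever
drop rows — intensities are never modified — so each filter is idempotent and
the detection-based filters commute.

Extractions (and hence intensities) scale with culture surface area, so the
module also provides the proportional solvent-volume rule used at the bench
(30 ul for a 3.5-mm-diameter well) and per-sample intensity scaling to
a.u./mm2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Tuple

from .feature_io import FeatureTable

__all__ = [
    "FilterConfig",
    "BLOOD_MATRIX_MIN_INTENSITY",
    "filter_q",
    "filter_replicate_presence",
    "filter_blank",
    "filter_min_intensity",
    "apply_filter_cascade",
    "scale_by_surface_area",
    "solvent_volume_for_area",
    "REFERENCE_WELL_DIAMETER_MM",
    "REFERENCE_WELL_VOLUME_UL",
]

log = logging.getLogger(__name__)

#: Intensity floor for high-background (blood) matrix experiments.
BLOOD_MATRIX_MIN_INTENSITY = 60_000.0


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade.

    q_mode selects how the q-value threshold is read: ``"keep-significant"``
    (default) removes features with q > threshold; ``"literal"``
    removes q < threshold, the verbatim reading of the source protocol
    (almost certainly a typo, but kept available).
    """

    q_threshold: float = 0.05
    replicate_fraction: float = 0.66
    min_intensity: float = 5_000.0
    q_mode: str = "keep-significant"
    detection_floor: float = 0.0  # intensity strictly above this counts as detected

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_threshold <= 1.0):
            raise ValueError("q_threshold must be in [0, 1]")
        if not (0.0 < self.replicate_fraction <= 1.0):
            raise ValueError("replicate_fraction must be in (0, 1]")
        if not math.isfinite(self.min_intensity):
            raise ValueError("min_intensity must be finite")
        if self.q_mode not in ("keep-significant", "literal"):
            raise ValueError(f"unknown q_mode {self.q_mode!r}")

    def for_blood_matrix(self) -> "FilterConfig":
        """Same cascade with the 60,000 a.u. floor for blood-matrix data."""
        return replace(self, min_intensity=BLOOD_MATRIX_MIN_INTENSITY)


def filter_q(table: FeatureTable, cfg: FilterConfig = FilterConfig()) -> FeatureTable:
    """Drop features by their alignment q-value.

    Features without a q-value pass unchanged (logged).  Under the default
    ``keep-significant`` mode, q > threshold is removed; under
    ``literal``, q < threshold is removed.
    """
    q = table.features["q_value"]
    n_missing = int(q.isna().sum())
    if n_missing:
        log.info("filter_q: %d features lack a q-value and pass unchanged", n_missing)
    if cfg.q_mode == "keep-significant":
        keep = q.isna() | (q <= cfg.q_threshold)
    else:  # literal: remove q < threshold
        keep = q.isna() | (q >= cfg.q_threshold)
    return table.subset(list(table.features.index[keep]))


def _condition_presence(table: FeatureTable, cfg: FilterConfig):
    """Fraction of non-blank replicates detecting each feature, per condition."""
    det = table.detected(cfg.detection_floor)
    fractions = {}
    for condition in table.conditions:
        ids = table.sample_ids(condition)
        if not ids:
            raise ValueError(f"condition {condition!r} has no non-blank samples")
        fractions[condition] = det[ids].mean(axis=1)
    return fractions


def filter_replicate_presence(table: FeatureTable, cfg: FilterConfig = FilterConfig()) -> FeatureTable:
    """Keep features detected in >= ``replicate_fraction`` of the replicates
    of at least one condition (blanks are not a condition).

    With the default 0.66, detection in 2 of 3 replicates (0.667) passes.
    """
    if not table.conditions:
        raise ValueError("no non-blank conditions in the table")
    fractions = _condition_presence(table, cfg)
    keep = None
    for frac in fractions.values():
        ok = frac >= cfg.replicate_fraction
        keep = ok if keep is None else (keep | ok)
    return table.subset(list(table.features.index[keep]))


def filter_blank(table: FeatureTable, cfg: FilterConfig = FilterConfig()) -> FeatureTable:
    """Remove features detected in any blank (solvent-control) sample.

    With no blanks declared the table passes unchanged with a warning.
    """
    blank_ids = table.sample_ids(blanks=True)
    if not blank_ids:
        warnings.warn("filter_blank: no blank samples declared; table unchanged")
        return table.copy()
    in_blank = table.detected(cfg.detection_floor)[blank_ids].any(axis=1)
    return table.subset(list(table.features.index[~in_blank]))


def filter_min_intensity(table: FeatureTable, cfg: FilterConfig = FilterConfig()) -> FeatureTable:
    """Remove features whose maximum intensity over non-blank samples is
    strictly below ``min_intensity`` (a maximum exactly at the floor is kept)."""
    ids = table.sample_ids()
    if not ids:
        raise ValueError("no non-blank samples in the table")
    peak = table.intensities[ids].max(axis=1)
    keep = peak >= cfg.min_intensity
    return table.subset(list(table.features.index[keep]))


def apply_filter_cascade(
    table: FeatureTable, cfg: FilterConfig = FilterConfig()
) -> Tuple[FeatureTable, Dict[str, int]]:
    """Run q -> replicate-presence -> blank -> minimum-intensity, in that order.

    Returns the filtered table and the feature count after each stage.
    """
    counts: Dict[str, int] = {"input": table.n_features}
    table = filter_q(table, cfg)
    counts["q"] = table.n_features
    table = filter_replicate_presence(table, cfg)
    counts["replicate_presence"] = table.n_features
    table = filter_blank(table, cfg)
    counts["blank"] = table.n_features
    table = filter_min_intensity(table, cfg)
    counts["min_intensity"] = table.n_features
    return table, counts


def scale_by_surface_area(table: FeatureTable) -> FeatureTable:
    """Divide each sample's intensities by its culture surface area (a.u./mm2).

    Every non-blank sample must declare a positive ``surface_area_mm2``;
    blanks without an area are left unscaled.
    """
    out = table.copy()
    areas = out.samples["surface_area_mm2"]
    blank = out.samples["is_blank"].astype(bool)
    bad = [
        sid
        for sid in out.samples.index[~blank]
        if not (areas[sid] > 0)  # catches NaN and non-positive
    ]
    if bad:
        raise ValueError(f"missing or non-positive surface area for sample(s): {bad}")
    for sid in out.samples.index:
        a = areas[sid]
        if a > 0:
            out.intensities[sid] = out.intensities[sid] / a
    return out


#: Diameter of the standard microscale culture well, mm.
REFERENCE_WELL_DIAMETER_MM = 3.5
#: Solvent volume used for that standard well, ul.
REFERENCE_WELL_VOLUME_UL = 30.0


def solvent_volume_for_area(area_mm2: float) -> float:
    """Extraction solvent volume (ul) proportional to culture surface area.

    The rate is anchored at 30 ul for a 3.5-mm-diameter well (9.6211 mm2);
    ten 10-mm-diameter cores (785.40 mm2) give 2,449 ul = 2.449 ml.
    """
    if area_mm2 < 0:
        raise ValueError("surface area must be >= 0")
    reference_area = math.pi * (REFERENCE_WELL_DIAMETER_MM / 2.0) ** 2
    return area_mm2 * REFERENCE_WELL_VOLUME_UL / reference_area
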