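"""Exact-mass putative annotation with adduct grouping and compatibility resolution.

Candidate generation matches every feature against every (compound, adduct)
pair of a database and an adduct set, keeping matches with ppm error strictly
below the gate (default 10 ppm, typical for TOF accuracy).  Candidates for
one compound are then clustered on retention time — co-eluting adducts of one
neutral molecule must elute together (default span 45 s).  Finally, features
claimed by several compounds are resolved in favour of the compound whose
adduct group explains the most co-eluting features; this operationalises the
rule that a putative identification is discarded when its proposed adducts
are incompatible with the rest of the spectrum.

Structural isomers (identical formulas under different names) are merged into
one composite "A or B" label before matching, since exact mass cannot tell
them apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .chem_mass import (
    AdductSpec,
    DEFAULT_NEGATIVE_ADDUCTS,
    adduct_mz,
    format_formula,
    monoisotopic_mass,
    ppm_error,
)
from .feature_io import CompoundRecord, FeatureTable

__all__ = [
    "AnnotationConfig",
    "Annotation",
    "merge_isomers",
    "annotate_features",
    "group_adducts_by_rt",
    "resolve_compatibility",
    "count_distinct_metabolites",
    "confirm_by_msms",
    "annotate_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationConfig:
    """Gates of the annotation chain (all strictly-less-than comparisons)."""

    ppm_tolerance: float = 10.0
    rt_window_s: float = 45.0
    msms_mz_tolerance: float = 0.05
    msms_rt_tolerance_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("ppm_tolerance", "rt_window_s", "msms_mz_tolerance", "msms_rt_tolerance_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Annotation:
    """One (feature, compound, adduct) assignment with its mass error."""

    feature_id: str
    compound: str
    adduct: str
    predicted_mz: float
    observed_mz: float
    error_ppm: float
    rt_s: float
    group_id: Optional[int] = None


def merge_isomers(db: Sequence[CompoundRecord]) -> List[CompoundRecord]:
    """Collapse database entries with identical formulas into composite labels.

    ``["Desacetylaustin", "Austinol"]`` with one formula becomes a single
    record named ``"Austinol or Desacetylaustin"`` (names sorted for
    determinism).  Entries already unique pass through unchanged.
    """
    by_formula: Dict[str, List[CompoundRecord]] = {}
    for rec in db:
        by_formula.setdefault(format_formula(rec.formula), []).append(rec)
    merged: List[CompoundRecord] = []
    for formula_str, records in by_formula.items():
        if len(records) == 1:
            merged.append(records[0])
        else:
            names = sorted({r.name for r in records})
            merged.append(
                CompoundRecord(
                    name=" or ".join(names),
                    formula=records[0].formula,
                    source=";".join(sorted({r.source for r in records if r.source})),
                )
            )
    return merged


def annotate_features(
    table: FeatureTable,
    db: Sequence[CompoundRecord],
    adducts: Sequence[AdductSpec] = DEFAULT_NEGATIVE_ADDUCTS,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> List[Annotation]:
    """Emit every candidate (feature, compound, adduct) within the ppm gate.

    A feature may carry several candidates at this stage; the list is sorted
    by ascending error.  Group ids are not assigned yet.
    """
    if not list(adducts):
        raise ValueError("empty adduct set")
    if not list(db):
        raise ValueError("empty compound database")
    compounds = merge_isomers(db)
    masses = [(rec, monoisotopic_mass(rec.formula)) for rec in compounds]
    predicted = [
        (rec.name, spec.name, adduct_mz(mass, spec))
        for rec, mass in masses
        for spec in adducts
    ]
    candidates: List[Annotation] = []
    feats = table.features
    for feature_id, observed, rt in zip(feats.index, feats["mz"], feats["rt_s"]):
        for compound_name, adduct_name, pred in predicted:
            err = ppm_error(observed, pred)
            if err < cfg.ppm_tolerance:
                candidates.append(
                    Annotation(
                        feature_id=str(feature_id),
                        compound=compound_name,
                        adduct=adduct_name,
                        predicted_mz=pred,
                        observed_mz=float(observed),
                        error_ppm=err,
                        rt_s=float(rt),
                    )
                )
    candidates.sort(key=lambda a: (a.error_ppm, a.feature_id, a.compound, a.adduct))
    return candidates


def _split_by_span(rts: np.ndarray, order: np.ndarray, window: float) -> List[np.ndarray]:
    """Single-linkage 1-D clustering with a hard span cap.

    Clusters are first cut at gaps > window; any cluster whose total span
    still exceeds the window is split at its largest internal gap until every
    cluster spans <= window.  Deterministic for a fixed input order.
    """
    groups: List[np.ndarray] = []
    pending = [order]
    while pending:
        idx = pending.pop()
        r = rts[idx]
        if len(idx) == 1 or (r.max() - r.min()) <= window:
            groups.append(idx)
            continue
        gaps = np.diff(r)
        cut = int(np.argmax(gaps)) + 1
        pending.append(idx[:cut])
        pending.append(idx[cut:])
    groups.sort(key=lambda g: rts[g].min())
    return groups


def group_adducts_by_rt(
    candidates: Sequence[Annotation], cfg: AnnotationConfig = AnnotationConfig()
) -> List[Annotation]:
    """Partition same-compound candidates into retention-time-coherent groups.

    Within one compound, candidates are clustered by single linkage on RT and
    each group's pairwise RT span is capped at ``rt_window_s`` (clusters that
    violate the cap are split at their largest gap).  Singletons are allowed.
    Returns copies with ``group_id`` assigned; ids are sequential over
    compounds in name order, groups in RT order.
    """
    by_compound: Dict[str, List[Annotation]] = {}
    for cand in candidates:
        by_compound.setdefault(cand.compound, []).append(cand)
    grouped: List[Annotation] = []
    group_id = 0
    for compound in sorted(by_compound):
        members = by_compound[compound]
        rts = np.array([m.rt_s for m in members], dtype=float)
        order = np.argsort(rts, kind="stable")
        for idx in _split_by_span(rts, order, cfg.rt_window_s):
            for i in idx:
                grouped.append(replace(members[int(i)], group_id=group_id))
            group_id += 1
    return grouped


def resolve_compatibility(
    grouped: Sequence[Annotation], cfg: AnnotationConfig = AnnotationConfig()
) -> List[Annotation]:
    """Resolve features claimed by several compounds; one annotation per feature.

    For each contested feature the compound whose RT group explains the most
    co-eluting features wins; ties go to the group with the lowest mean ppm
    error, then to compound-name order (logged).  Discarded candidates are
    logged with the reason.  Output count never exceeds input count.
    """
    group_members: Dict[int, List[Annotation]] = {}
    for ann in grouped:
        if ann.group_id is None:
            raise ValueError("resolve_compatibility requires grouped annotations")
        group_members.setdefault(ann.group_id, []).append(ann)
    group_size = {gid: len(m) for gid, m in group_members.items()}
    group_mean_err = {gid: float(np.mean([a.error_ppm for a in m])) for gid, m in group_members.items()}

    by_feature: Dict[str, List[Annotation]] = {}
    for ann in grouped:
        by_feature.setdefault(ann.feature_id, []).append(ann)

    final: List[Annotation] = []
    for feature_id, anns in by_feature.items():
        ranked = sorted(
            anns,
            key=lambda a: (-group_size[a.group_id], group_mean_err[a.group_id], a.compound, a.adduct),
        )
        winner = ranked[0]
        final.append(winner)
        for loser in ranked[1:]:
            log.info(
                "feature %s: discarded %s (%s, group of %d) in favour of %s (%s, group of %d)",
                feature_id,
                loser.compound,
                loser.adduct,
                group_size[loser.group_id],
                winner.compound,
                winner.adduct,
                group_size[winner.group_id],
            )
    # contract: every emitted annotation is inside the ppm gate
    for ann in final:
        assert ann.error_ppm < cfg.ppm_tolerance
    final.sort(key=lambda a: (a.compound, a.observed_mz, a.feature_id))
    return final


def count_distinct_metabolites(annotations: Sequence[Annotation]) -> int:
    """Number of distinct compound labels among final annotations."""
    return len({a.compound for a in annotations})


def confirm_by_msms(
    observed_fragments: Sequence[float],
    observed_rt_s: float,
    reference_fragments: Sequence[float],
    reference_rt_s: float,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> bool:
    """Confirm a putative identification against a standard's MS/MS spectrum.

    Confirmed iff the retention-time difference is strictly below 30 s and
    every reference fragment has an observed fragment within 0.05 m/z
    (defaults; both strict).
    """
    if not list(reference_fragments):
        raise ValueError("reference fragment list is empty")
    if abs(observed_rt_s - reference_rt_s) >= cfg.msms_rt_tolerance_s:
        return False
    obs = np.asarray(list(observed_fragments), dtype=float)
    if obs.size == 0:
        return False
    for ref in reference_fragments:
        if np.min(np.abs(obs - ref)) >= cfg.msms_mz_tolerance:
            return False
    return True


def annotate_table(
    table: FeatureTable,
    db: Sequence[CompoundRecord],
    adducts: Sequence[AdductSpec] = DEFAULT_NEGATIVE_ADDUCTS,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> List[Annotation]:
    """The full chain: candidates -> RT grouping -> compatibility resolution."""
    candidates = annotate_features(table, db, adducts, cfg)
    grouped = group_adducts_by_rt(candidates, cfg)
    return resolve_compatibility(grouped, cfg)
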