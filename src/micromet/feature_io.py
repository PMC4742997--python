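"""Tabular I/O for aligned feature tables, sample metadata, compound databases
and annotation reports, plus the packaged worked-example data.

Conventions
-----------
* All files are comma-separated UTF-8 text with a header row and "." decimals.
* Retention time is stored in **seconds** everywhere.
* An intensity of 0 encodes "not detected"; downstream presence calls key off
  this encoding, so readers refuse negative intensities and fill missing
  values with 0.
* In reports, m/z is printed to 3 decimals and ppm error to 2 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem_mass import format_formula, parse_formula

__all__ = [
    "FEATURE_COLUMNS",
    "METADATA_COLUMNS",
    "FeatureTable",
    "CompoundRecord",
    "read_feature_table",
    "write_feature_table",
    "read_compound_db",
    "write_compound_db",
    "load_reference_compounds",
    "load_reference_annotations",
    "reference_annotation_inconsistencies",
    "write_annotation_table",
    "read_annotation_table",
]

FEATURE_COLUMNS = ("feature_id", "mz", "rt_s", "q_value")
METADATA_COLUMNS = ("sample_id", "condition", "replicate", "is_blank", "surface_area_mm2")


class FeatureTableError(ValueError):
    """Inconsistent feature-table input."""


@dataclass
class FeatureTable:
    """An aligned LC-MS feature table: features x samples plus sample metadata.

    Attributes
    ----------
    features : DataFrame indexed by ``feature_id`` with columns ``mz`` (> 0),
        ``rt_s`` (>= 0, seconds) and ``q_value`` ([0, 1] or NaN).
    intensities : DataFrame indexed like ``features`` with one column per
        ``sample_id``; values >= 0, 0 meaning not detected.
    samples : DataFrame indexed by ``sample_id`` with columns ``condition``,
        ``replicate``, ``is_blank`` and optional ``surface_area_mm2``.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- consistency ---------------------------------------------------
    def validate(self) -> None:
        f, x, s = self.features, self.intensities, self.samples
        if f.index.has_duplicates:
            dupes = f.index[f.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature_id(s): {dupes}")
        if s.index.has_duplicates:
            raise FeatureTableError("duplicate sample_id(s) in metadata")
        if not f.index.equals(x.index):
            raise FeatureTableError("features and intensities indexes differ")
        unknown = [c for c in x.columns if c not in s.index]
        if unknown:
            raise FeatureTableError(f"intensity column(s) not in sample metadata: {unknown}")
        if (x.to_numpy(dtype=float) < 0).any():
            raise FeatureTableError("negative intensity encountered (0 encodes not-detected)")
        if len(f) and (f["mz"].to_numpy(dtype=float) <= 0).any():
            raise FeatureTableError("all m/z values must be positive")
        if len(f) and (f["rt_s"].to_numpy(dtype=float) < 0).any():
            raise FeatureTableError("retention times must be >= 0 seconds")
        nonblank = s[~s["is_blank"].astype(bool)]
        if nonblank["condition"].isna().any() or (nonblank["condition"] == "").any():
            raise FeatureTableError("every non-blank sample needs a condition label")

    # -- views ----------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.features.index)

    @property
    def conditions(self) -> List[str]:
        """Condition labels of non-blank samples, in metadata order."""
        nb = self.samples[~self.samples["is_blank"].astype(bool)]
        return list(dict.fromkeys(nb["condition"]))

    def sample_ids(self, condition: Optional[str] = None, *, blanks: bool = False) -> List[str]:
        s = self.samples
        mask = s["is_blank"].astype(bool) if blanks else ~s["is_blank"].astype(bool)
        if condition is not None:
            if condition not in set(s.loc[~s["is_blank"].astype(bool), "condition"]):
                raise KeyError(f"unknown condition {condition!r}")
            mask &= s["condition"] == condition
        return list(s.index[mask])

    def detected(self, floor: float = 0.0) -> pd.DataFrame:
        """Boolean detection matrix (intensity strictly above ``floor``)."""
        return self.intensities > floor

    def subset(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Order-preserving subset of features (sample set unchanged)."""
        keep = [fid for fid in self.features.index if fid in set(feature_ids)]
        return FeatureTable(
            self.features.loc[keep].copy(),
            self.intensities.loc[keep].copy(),
            self.samples.copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy(), self.samples.copy())

    def equals(self, other: "FeatureTable", *, rtol: float = 0.0, atol: float = 1e-9) -> bool:
        try:
            pd.testing.assert_frame_equal(self.features, other.features, rtol=rtol, atol=atol)
            pd.testing.assert_frame_equal(self.intensities, other.intensities, rtol=rtol, atol=atol)
            pd.testing.assert_frame_equal(self.samples, other.samples, rtol=rtol, atol=atol)
        except AssertionError:
            return False
        return True


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str, "condition": str})
    missing = [c for c in ("sample_id", "condition", "replicate", "is_blank") if c not in meta.columns]
    if missing:
        raise FeatureTableError(f"metadata is missing column(s): {missing}")
    meta["is_blank"] = meta["is_blank"].map(_parse_bool)
    meta["replicate"] = meta["replicate"].astype(int)
    if "surface_area_mm2" not in meta.columns:
        meta["surface_area_mm2"] = np.nan
    meta["surface_area_mm2"] = pd.to_numeric(meta["surface_area_mm2"])
    return meta.set_index("sample_id")[["condition", "replicate", "is_blank", "surface_area_mm2"]]


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FeatureTableError(f"cannot interpret {v!r} as a boolean blank flag")


def read_feature_table(features_path, metadata_path) -> FeatureTable:
    """Read an aligned feature table and its sample metadata from CSV.

    The features file carries ``feature_id, mz, rt_s, q_value`` followed by one
    intensity column per sample; every intensity column must be declared in the
    metadata, missing intensities are read as 0, and negative intensities are
    rejected.
    """
    samples = _read_metadata(metadata_path)
    raw = pd.read_csv(features_path, dtype={"feature_id": str})
    missing = [c for c in ("feature_id", "mz", "rt_s") if c not in raw.columns]
    if missing:
        raise FeatureTableError(f"features file is missing column(s): {missing}")
    if "q_value" not in raw.columns:
        raw["q_value"] = np.nan
    if raw["feature_id"].duplicated().any():
        dupes = raw.loc[raw["feature_id"].duplicated(), "feature_id"].tolist()
        raise FeatureTableError(f"duplicate feature_id(s): {dupes}")
    raw = raw.set_index("feature_id")
    sample_cols = [c for c in raw.columns if c not in ("mz", "rt_s", "q_value")]
    unknown = [c for c in sample_cols if c not in samples.index]
    if unknown:
        raise FeatureTableError(f"intensity column(s) not declared in metadata: {unknown}")
    features = raw[["mz", "rt_s", "q_value"]].astype(float)
    intensities = raw[sample_cols].astype(float).fillna(0.0)
    # samples declared in metadata but absent from the features file: all zero
    for sid in samples.index:
        if sid not in intensities.columns:
            intensities[sid] = 0.0
    intensities = intensities[list(samples.index)]
    return FeatureTable(features, intensities, samples)


def write_feature_table(table: FeatureTable, features_path, metadata_path) -> None:
    """Write a :class:`FeatureTable` as the features/metadata CSV pair (lossless)."""
    out = pd.concat([table.features, table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(features_path)
    meta = table.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path)


# ---------------------------------------------------------------------------
# compound databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """A named compound with a parsed elemental formula."""

    name: str
    formula: Dict[str, int] = field(hash=False)
    source: str = ""

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula)


class CompoundDbError(ValueError):
    """Unparseable compound-database input."""


def read_compound_db(path, *, lenient: bool = False) -> List[CompoundRecord]:
    """Read a ``name, formula, source`` CSV into compound records.

    Duplicate (name, formula) rows are collapsed with a warning.  A row whose
    formula does not parse raises :class:`CompoundDbError` naming the line;
    in lenient mode it is skipped with a warning instead.
    """
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        return []
    for col in ("name", "formula"):
        if col not in df.columns:
            raise CompoundDbError(f"compound database is missing column {col!r}")
    records: List[CompoundRecord] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            formula = parse_formula(row.formula)
        except ValueError as exc:
            msg = f"line {i}: cannot parse formula {row.formula!r} for {row.name!r}: {exc}"
            if lenient:
                warnings.warn(msg)
                continue
            raise CompoundDbError(msg) from exc
        key = (row.name, format_formula(formula))
        if key in seen:
            warnings.warn(f"line {i}: duplicate compound {row.name!r} ({key[1]}) collapsed")
            continue
        seen.add(key)
        source = getattr(row, "source", "") or ""
        records.append(CompoundRecord(name=row.name, formula=formula, source=source))
    return records


def write_compound_db(records: Sequence[CompoundRecord], path) -> None:
    pd.DataFrame(
        {
            "name": [r.name for r in records],
            "formula": [r.formula_str for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, index=False)


def load_reference_compounds() -> List[CompoundRecord]:
    """The curated 19-compound *A. nidulans* secondary-metabolite database.

    Formulas are curated from the literature for the named metabolites; they
    back the packaged worked example and the simulator defaults.
    """
    with resources.as_file(resources.files("micromet.data") / "nidulans_compounds.csv") as p:
        return read_compound_db(p)


# ---------------------------------------------------------------------------
# worked-example annotation table
# ---------------------------------------------------------------------------

def load_reference_annotations() -> pd.DataFrame:
    """The packaged worked-example annotation report (33 rows, 19 metabolites).

    Negative-mode putative annotations of *A. nidulans* features: columns
    ``feature_id, annotation, mz, adduct, error_ppm`` exactly as published.
    Note the emericellin pair flagged by :func:`reference_annotation_inconsistencies`.
    """
    with resources.as_file(resources.files("micromet.data") / "nidulans_annotation_report.csv") as p:
        df = pd.read_csv(p, dtype={"annotation": str, "adduct": str})
    df["feature_id"] = df["feature_id"].astype(int)
    return df


def reference_annotation_skeleton() -> "FeatureTable":
    """The worked example recast as a single-sample feature table.

    Printed m/z values become features; retention times are constructed so
    that rows of one compound share an anchor within the 45-s adduct window
    while different compounds are well separated (the published report prints
    no retention times).  Used to exercise the annotation chain end to end.
    """
    t1 = load_reference_annotations()
    anchors = {c: 100.0 + 200.0 * i for i, c in enumerate(dict.fromkeys(t1["annotation"]))}
    rts = [anchors[c] + 10.0 * (k % 3) for k, c in enumerate(t1["annotation"])]
    features = pd.DataFrame(
        {"mz": t1["mz"].to_numpy(float), "rt_s": rts, "q_value": 0.01},
        index=pd.Index(t1["feature_id"].astype(str), name="feature_id"),
    )
    samples = pd.DataFrame(
        {"condition": ["gmm"], "replicate": [1], "is_blank": [False],
         "surface_area_mm2": [np.pi * 1.75**2]},
        index=pd.Index(["s1"], name="sample_id"),
    )
    intensities = pd.DataFrame({"s1": 1e5}, index=features.index)
    return FeatureTable(features, intensities, samples)


def reference_annotation_inconsistencies() -> List[Tuple[int, int]]:
    """Feature-id pairs in the worked example that violate the dimer mass relation.

    The emericellin rows 25 ([M-H]- at 393.172) and 26 ([2M-H]- at 815.386)
    cannot both derive from one neutral mass: 2*393.172-ish is ~786.35, not
    815.386.  Row 26 is consistent with the literature formula C25H28O5; the
    report is reproduced verbatim rather than second-guessed.
    """
    return [(25, 26)]


# ---------------------------------------------------------------------------
# annotation reports
# ---------------------------------------------------------------------------

ANNOTATION_REPORT_COLUMNS = ("feature_id", "annotation", "mz", "adduct", "error_ppm", "rt_s", "group_id")


def write_annotation_table(annotations, path) -> None:
    """Write annotations as a report CSV shaped like the worked example.

    Accepts a sequence of :class:`micromet.annotation.Annotation` or a
    DataFrame with the report columns.  Rows are ordered by compound label
    then m/z; m/z is printed to 3 decimals and the error to 2.
    """
    if isinstance(annotations, pd.DataFrame):
        df = annotations.copy()
    else:
        df = pd.DataFrame(
            {
                "feature_id": [a.feature_id for a in annotations],
                "annotation": [a.compound for a in annotations],
                "mz": [a.observed_mz for a in annotations],
                "adduct": [a.adduct for a in annotations],
                "error_ppm": [a.error_ppm for a in annotations],
                "rt_s": [a.rt_s for a in annotations],
                "group_id": [a.group_id for a in annotations],
            }
        )
    for col in ANNOTATION_REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(ANNOTATION_REPORT_COLUMNS)].sort_values(
        ["annotation", "mz"], kind="stable"
    )
    df["mz"] = df["mz"].map(lambda v: f"{v:.3f}")
    df["error_ppm"] = df["error_ppm"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False)


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"feature_id": str, "annotation": str, "adduct": str})
    return df
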