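import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from micromet.feature_io import FeatureTable, load_reference_compounds, load_reference_annotations

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_table(
    intensity_rows,
    *,
    mz=None,
    rt=None,
    q=None,
    conditions=("A", "A", "A", "B", "B", "B"),
    blanks=0,
    surface_area=9.6211,
):
    """Build a small FeatureTable from a list of per-feature intensity rows.

    Each row covers the non-blank samples (grouped by ``conditions``) followed
    by ``blanks`` blank samples.
    """
    intensity_rows = [list(r) for r in intensity_rows]
    n_feat = len(intensity_rows)
    n_cond_samples = len(conditions)
    sample_ids, meta = [], []
    counts = {}
    for c in conditions:
        counts[c] = counts.get(c, 0) + 1
        sid = f"{c}_r{counts[c]}"
        sample_ids.append(sid)
        meta.append({"sample_id": sid, "condition": c, "replicate": counts[c],
                     "is_blank": False, "surface_area_mm2": surface_area})
    for b in range(1, blanks + 1):
        sid = f"blank_r{b}"
        sample_ids.append(sid)
        meta.append({"sample_id": sid, "condition": "solvent-blank", "replicate": b,
                     "is_blank": True, "surface_area_mm2": surface_area})
    for row in intensity_rows:
        assert len(row) == n_cond_samples + blanks
    fids = [f"F{i+1:03d}" for i in range(n_feat)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(200.0, 800.0, n_feat),
            "rt_s": rt if rt is not None else np.linspace(100.0, 2000.0, n_feat),
            "q_value": q if q is not None else [0.01] * n_feat,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    intensities = pd.DataFrame(intensity_rows, index=features.index, columns=sample_ids, dtype=float)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return FeatureTable(features, intensities, samples)


@pytest.fixture(scope="session")
def reference_db():
    return load_reference_compounds()


@pytest.fixture(scope="session")
def annotation_report():
    return load_reference_annotations()


@pytest.fixture()
def report_skeleton():
    """The worked example as a feature table: printed m/z plus constructed RTs
    in which same-compound rows share an anchor within the grouping window."""
    from micromet.feature_io import reference_annotation_skeleton

    return reference_annotation_skeleton()
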