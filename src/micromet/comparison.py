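"""Condition presence calls, two-condition zone (Venn) classification and
the group statistics used to compare metabolite levels.

A feature is "present" in a condition when it is detected (intensity > 0) in
at least the configured fraction (default 66%) of that condition's non-blank
replicates — the same rule as the replicate-presence filter.  Two-condition
comparison partitions features into the Venn zones A-only / shared / B-only /
neither; "produced primarily on A" is operationalised as present-on-A and
not-present-on-B.

Statistics: tie-corrected Kruskal-Wallis H with a chi-square p-value for
multi-group comparisons, Dunn's z post hoc with comparison-count (Bonferroni)
adjustment, and the pooled-variance unpaired Student t for two groups.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import FeatureTable
from .preprocess import FilterConfig

__all__ = [
    "presence_call",
    "classify_zones",
    "ZONES",
    "kruskal_wallis",
    "dunn_posthoc",
    "two_sample_t",
]

ZONES = ("A-only", "shared", "B-only", "neither")


def presence_call(
    table: FeatureTable, condition: str, cfg: FilterConfig = FilterConfig()
) -> pd.Series:
    """Boolean per-feature presence call for one condition.

    Present iff detected in >= ``cfg.replicate_fraction`` of the condition's
    non-blank replicates (2 of 3 passes at the 0.66 default).
    """
    ids = table.sample_ids(condition)  # raises KeyError for unknown condition
    det = table.detected(cfg.detection_floor)[ids]
    return (det.mean(axis=1) >= cfg.replicate_fraction).rename(condition)


def classify_zones(
    table: FeatureTable,
    condition_a: str,
    condition_b: str,
    cfg: FilterConfig = FilterConfig(),
    *,
    exclude_condition: Optional[str] = None,
) -> pd.DataFrame:
    """Partition features into Venn zones between two conditions.

    ``A-only``: present in A and not B; ``B-only`` symmetric; ``shared``:
    both; ``neither``: neither.  When ``exclude_condition`` is given (e.g. a
    matrix-alone control), features present in it are removed before
    classification.  Swapping A and B exactly swaps the A-only/B-only labels.
    """
    if condition_a == condition_b:
        raise ValueError("the two conditions must differ")
    if exclude_condition is not None:
        control = presence_call(table, exclude_condition, cfg)
        table = table.subset(list(control.index[~control]))
    in_a = presence_call(table, condition_a, cfg)
    in_b = presence_call(table, condition_b, cfg)
    zone = np.where(
        in_a & ~in_b, "A-only",
        np.where(~in_a & in_b, "B-only", np.where(in_a & in_b, "shared", "neither")),
    )
    return pd.DataFrame(
        {"zone": zone, "present_a": in_a, "present_b": in_b}, index=in_a.index
    )


def _validated_groups(groups: Sequence[Sequence[float]], min_groups: int) -> List[np.ndarray]:
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    return arrays


#: Largest pooled sample size for which the Kruskal-Wallis p is computed by
#: exhaustive enumeration rather than the chi-square approximation.
EXACT_KW_MAX_N = 10


def _exact_kw_pvalue(arrays: List[np.ndarray], h_obs: float) -> float:
    """P(H >= h_obs) over all distinct assignments of the pooled values.

    Because the pooled mid-ranks and the tie correction are permutation
    invariant, H is a monotone function of sum(R_i^2 / n_i); the enumeration
    compares that statistic.  Feasible for pooled N around 10.
    """
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    obs_stat = sum(
        np.sum(ranks[start : start + n]) ** 2 / n
        for start, n in zip(np.cumsum([0] + sizes[:-1]), sizes)
    )
    from itertools import combinations

    count = total = 0

    def recurse(remaining: Tuple[int, ...], gi: int, acc: float) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            stat = acc + np.sum(ranks[list(remaining)]) ** 2 / sizes[-1]
            total += 1
            if stat >= obs_stat - 1e-9:
                count += 1
            return
        for chosen in combinations(remaining, sizes[gi]):
            rest = tuple(i for i in remaining if i not in set(chosen))
            recurse(rest, gi + 1, acc + np.sum(ranks[list(chosen)]) ** 2 / sizes[gi])

    recurse(tuple(range(pooled.size)), 0, 0.0)
    return count / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]], p_method: str = "auto"
) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with an exact or chi-square p-value.

    ``p_method="auto"`` (default) enumerates every regrouping of the pooled
    values when the pooled sample size is <= 10 — the chi-square tail is a
    poor approximation at the replicate counts of microscale designs — and
    falls back to the chi-square distribution with k - 1 df otherwise;
    ``"chi2"`` and ``"exact"`` force either route.  Identical values across
    all groups give H = 0, p = 1.
    """
    if p_method not in ("auto", "chi2", "exact"):
        raise ValueError(f"unknown p_method {p_method!r}")
    arrays = _validated_groups(groups, min_groups=2)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p_chi2 = stats.kruskal(*arrays)
    h = float(h)
    use_exact = p_method == "exact" or (p_method == "auto" and pooled.size <= EXACT_KW_MAX_N)
    if use_exact:
        return h, float(_exact_kw_pvalue(arrays, h))
    return h, float(p_chi2)


def dunn_posthoc(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Dunn's rank-based post hoc z for every pair of groups.

    z_ij = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p multiplied by
    the number of comparisons and capped at 1.
    """
    arrays = _validated_groups(groups, min_groups=2)
    k = len(arrays)
    if labels is None:
        labels = [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match the number of groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + a.size])))
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_comparisons = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            var = base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
            if var <= 0:  # everything tied
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "z": float(z),
                    "p_raw": float(p_raw),
                    "p_adjusted": float(min(1.0, p_raw * n_comparisons)),
                }
            )
    return pd.DataFrame(rows)


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Unpaired pooled-variance Student t with n1 + n2 - 2 df (two-sided p).

    Two identical constant samples compare as t = 0, p = 1.
    """
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def feature_group_test(
    table: FeatureTable, feature_id: str, cfg: FilterConfig = FilterConfig()
) -> Dict[str, object]:
    """Kruskal-Wallis across all conditions for one feature's intensities.

    Convenience used by the pipeline's per-feature statistics stage; returns
    the H statistic, p-value and per-condition means.
    """
    if feature_id not in table.features.index:
        raise KeyError(f"unknown feature {feature_id!r}")
    groups, labels = [], []
    for condition in table.conditions:
        ids = table.sample_ids(condition)
        groups.append(table.intensities.loc[feature_id, ids].to_numpy(dtype=float))
        labels.append(condition)
    h, p = kruskal_wallis(groups)
    return {
        "feature_id": feature_id,
        "H": h,
        "p_value": p,
        "condition_means": {c: float(np.mean(g)) for c, g in zip(labels, groups)},
    }
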