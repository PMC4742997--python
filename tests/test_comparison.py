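"""Presence calls, Venn zone classification, and group statistics with
independent oracles (exhaustive permutations, hand rank arithmetic)."""

import itertools

import numpy as np
import pytest
from scipy import stats

from micromet.comparison import (
    classify_zones,
    dunn_posthoc,
    kruskal_wallis,
    presence_call,
    two_sample_t,
)
from micromet.preprocess import FilterConfig
from micromet.synthetic_data import SimConfig, generate, score_presence

from conftest import make_table

CFG = FilterConfig()


class TestPresenceCall:
    def test_two_of_three_replicates_is_present(self):
        table = make_table([[5, 5, 0, 0, 0, 0]])
        assert presence_call(table, "A", CFG).loc["F001"]
        assert not presence_call(table, "B", CFG).loc["F001"]

    def test_zero_detection_is_absent(self):
        table = make_table([[0, 0, 0, 0, 0, 0]])
        assert not presence_call(table, "A", CFG).loc["F001"]

    def test_unknown_condition_rejected(self):
        with pytest.raises(KeyError):
            presence_call(make_table([[1] * 6]), "no-such-condition", CFG)

    def test_simulated_condition_specific_features_called_correctly(self, reference_db):
        names = [r.name for r in reference_db]
        mult = {
            "blood": {n: (1.0 if i < 10 else 0.0) for i, n in enumerate(names)},
            "gmm": {n: (0.0 if i < 10 else 1.0) for i, n in enumerate(names)},
        }
        table, truth = generate(
            SimConfig(seed=8, conditions=("blood", "gmm"), condition_multipliers=mult,
                      dropout_p=0.0, n_contaminants=0, replicates=3)
        )
        for condition in ("blood", "gmm"):
            s = score_presence(presence_call(table, condition, CFG), truth, condition)
            assert s.precision == 1.0 and s.recall == 1.0


class TestZoneClassification:
    def test_partition_and_symmetry(self):
        table = make_table(
            [
                [9, 9, 9, 0, 0, 0],  # A-only
                [9, 9, 9, 9, 9, 9],  # shared
                [0, 0, 0, 9, 9, 9],  # B-only
                [9, 0, 0, 0, 0, 9],  # neither (1/3 each)
            ]
        )
        z = classify_zones(table, "A", "B", CFG)
        assert list(z["zone"]) == ["A-only", "shared", "B-only", "neither"]
        swapped = classify_zones(table, "B", "A", CFG)
        assert list(swapped["zone"]) == ["B-only", "shared", "A-only", "neither"]

    def test_identical_conditions_rejected(self):
        with pytest.raises(ValueError):
            classify_zones(make_table([[1] * 6]), "A", "A", CFG)

    def test_control_features_excluded_first(self):
        table = make_table(
            [[9, 9, 9, 0, 0, 0, 9, 9, 9], [9, 9, 9, 0, 0, 0, 0, 0, 0]],
            conditions=("A", "A", "A", "B", "B", "B", "ctrl", "ctrl", "ctrl"),
        )
        z = classify_zones(table, "A", "B", CFG, exclude_condition="ctrl")
        assert list(z.index) == ["F002"] and list(z["zone"]) == ["A-only"]


def exhaustive_kw_pvalue(groups):
    """Exact permutation p for the Kruskal-Wallis H over all regroupings."""
    sizes = [len(g) for g in groups]
    pooled = list(np.concatenate([np.asarray(g, float) for g in groups]))
    h_obs, _ = stats.kruskal(*groups)
    count = total = 0
    for perm in itertools.permutations(range(len(pooled))):
        values = [pooled[i] for i in perm]
        regrouped, start = [], 0
        for n in sizes:
            regrouped.append(values[start : start + n])
            start += n
        h, _ = stats.kruskal(*regrouped)
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return count / total


class TestKruskalWallis:
    def test_identical_groups(self):
        assert kruskal_wallis([[5, 5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_hand_ranked_two_group_case(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.10, abs=1e-12)  # exact: 2 of 20 regroupings

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 2.0, 5.0], [3.0, 7.0, 8.0]],
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            [[1.0, 3.0], [2.0, 5.0], [4.0, 6.0, 7.0]],
            [[1.0, 6.0], [2.0, 5.0], [3.0, 4.0, 7.0, 8.0]],
        ],
    )
    def test_small_sample_p_matches_exhaustive_permutation_oracle(self, groups):
        _, p = kruskal_wallis(groups)
        assert abs(p - exhaustive_kw_pvalue(groups)) < 0.02

    def test_large_samples_fall_back_to_chi_square(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.normal(size=6)), list(rng.normal(1.0, 1.0, 6))]
        h, p = kruskal_wallis(groups)
        h_ref, p_ref = stats.kruskal(*groups)
        assert h == pytest.approx(float(h_ref)) and p == pytest.approx(float(p_ref))

    def test_tie_correction_matches_direct_midrank_formula(self):
        groups = [[1.0, 1.0, 2.0], [2.0, 3.0, 3.0]]
        h, _ = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n_total = len(pooled)
        rbar = (n_total + 1) / 2.0
        group_ranks = [ranks[:3], ranks[3:]]
        h_raw = 12.0 / (n_total * (n_total + 1)) * sum(
            len(r) * (np.mean(r) - rbar) ** 2 for r in group_ranks
        )
        _, tie_counts = np.unique(pooled, return_counts=True)
        correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
        assert h == pytest.approx(h_raw / correction, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestDunnPosthoc:
    def test_identical_groups_give_zero_z_unit_p(self):
        df = dunn_posthoc([[4, 4, 4], [4, 4, 4]])
        assert df.loc[0, "z"] == 0.0 and df.loc[0, "p_adjusted"] == 1.0

    def test_relabeling_flips_sign_keeps_p(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        d1 = dunn_posthoc([a, b])
        d2 = dunn_posthoc([b, a])
        assert d1.loc[0, "z"] == pytest.approx(-d2.loc[0, "z"])
        assert d1.loc[0, "p_adjusted"] == pytest.approx(d2.loc[0, "p_adjusted"])

    def test_three_group_hand_computation(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        df = dunn_posthoc(groups, labels=["a", "b", "c"])
        n_total = 6
        base_var = n_total * (n_total + 1) / 12.0  # no ties
        # mean ranks: 1.5, 3.5, 5.5
        z_ab = (1.5 - 3.5) / np.sqrt(base_var * (1 / 2 + 1 / 2))
        row = df[(df["group_i"] == "a") & (df["group_j"] == "b")].iloc[0]
        assert row["z"] == pytest.approx(z_ab, abs=1e-12)
        assert row["p_adjusted"] == pytest.approx(min(1.0, 3 * 2 * stats.norm.sf(abs(z_ab))), abs=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1, 2, 3]])


class TestTwoSampleT:
    def test_identical_samples(self):
        assert two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == (0.0, 1.0)
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swapping_groups_negates_t_preserves_p(self):
        x, y = [1.0, 2.0, 4.0], [5.0, 7.0, 8.0]
        t1, p1 = two_sample_t(x, y)
        t2, p2 = two_sample_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_pooled_variance_student_definition(self):
        x, y = [1.0, 2.0, 4.0], [5.0, 7.0, 8.0]
        t, p = two_sample_t(x, y)
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(float(t_ref)) and p == pytest.approx(float(p_ref))

    def test_large_shift_detected_at_triplicate_size(self):
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(10):
            x = rng.normal(0.0, 1.0, 3)
            y = rng.normal(10.0, 1.0, 3)
            _, p = two_sample_t(x, y)
            detected += p < 0.05
        assert detected >= 9

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])
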