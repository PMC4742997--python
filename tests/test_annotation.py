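"""Candidate generation, RT grouping, compatibility resolution, MS/MS check."""

import numpy as np
import pytest

from micromet.annotation import (
    Annotation,
    AnnotationConfig,
    annotate_features,
    annotate_table,
    confirm_by_msms,
    count_distinct_metabolites,
    group_adducts_by_rt,
    merge_isomers,
    resolve_compatibility,
)
from micromet.chem_mass import DEFAULT_NEGATIVE_ADDUCTS, EXTENDED_NEGATIVE_ADDUCTS
from micromet.feature_io import CompoundRecord
from micromet.synthetic_data import SimConfig, generate, score_annotations

from conftest import make_table

CFG = AnnotationConfig()


def single_feature_table(mz, rt=500.0):
    return make_table([[1e5] * 6], mz=[mz], rt=[rt])


class TestCandidateGeneration:
    def test_deprotonated_match_inside_gate(self):
        db = [CompoundRecord("Austinol intermediate", {"C": 25, "H": 30, "O": 7})]
        cands = annotate_features(single_feature_table(441.192), db, DEFAULT_NEGATIVE_ADDUCTS, CFG)
        assert len(cands) == 1
        assert cands[0].adduct == "[M-H]-" and cands[0].error_ppm < 10.0

    def test_far_off_mass_yields_nothing(self, reference_db):
        cands = annotate_features(single_feature_table(500.000), reference_db,
                                  DEFAULT_NEGATIVE_ADDUCTS, CFG)
        assert cands == []

    def test_candidates_sorted_by_ascending_error(self, reference_db):
        table, _ = generate(SimConfig(seed=5))
        cands = annotate_features(table, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG)
        errs = [c.error_ppm for c in cands]
        assert errs == sorted(errs)
        assert all(e < CFG.ppm_tolerance for e in errs)

    def test_empty_adduct_set_rejected(self, reference_db):
        with pytest.raises(ValueError, match="adduct"):
            annotate_features(single_feature_table(441.192), reference_db, [], CFG)

    def test_isomers_merge_into_composite_label(self):
        db = [
            CompoundRecord("Austinol", {"C": 25, "H": 30, "O": 8}),
            CompoundRecord("Desacetylaustin", {"C": 25, "H": 30, "O": 8}),
        ]
        merged = merge_isomers(db)
        assert len(merged) == 1
        assert merged[0].name == "Austinol or Desacetylaustin"


def _cand(fid, compound, rt, adduct="[M-H]-", err=1.0):
    return Annotation(fid, compound, adduct, 400.0, 400.0004, err, rt)


class TestRtGrouping:
    def test_co_eluting_adducts_form_one_group(self):
        cands = [_cand("f1", "Diorcinol", 300.0), _cand("f2", "Diorcinol", 310.0, "[2M-H]-"),
                 _cand("f3", "Diorcinol", 320.0, "[2M+FA-H]-")]
        grouped = group_adducts_by_rt(cands, CFG)
        assert len({g.group_id for g in grouped}) == 1

    def test_window_exceeded_splits_groups(self):
        cands = [_cand("f1", "Diorcinol", 300.0), _cand("f2", "Diorcinol", 420.0, "[2M-H]-")]
        grouped = group_adducts_by_rt(cands, CFG)
        assert len({g.group_id for g in grouped}) == 2

    def test_every_group_span_is_capped(self, reference_db):
        table, _ = generate(SimConfig(seed=9))
        grouped = group_adducts_by_rt(
            annotate_features(table, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG), CFG
        )
        by_group = {}
        for g in grouped:
            by_group.setdefault(g.group_id, []).append(g.rt_s)
        for rts in by_group.values():
            assert max(rts) - min(rts) <= CFG.rt_window_s + 1e-9

    def test_simulated_adduct_clusters_match_truth(self, reference_db):
        table, truth = generate(SimConfig(seed=9))
        grouped = group_adducts_by_rt(
            annotate_features(table, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG), CFG
        )
        # features of one true compound end up in one group, and vice versa
        compound_of_group = {}
        for g in grouped:
            truth_compound = truth.loc[g.feature_id, "compound"]
            if truth_compound == g.compound:
                compound_of_group.setdefault(g.group_id, set()).add(truth_compound)
        for compounds in compound_of_group.values():
            assert len(compounds) == 1


class TestCompatibilityResolution:
    def test_larger_co_eluting_group_wins(self):
        cands = [
            _cand("f1", "CompoundA", 300.0), _cand("f2", "CompoundA", 310.0, "[2M-H]-"),
            _cand("f3", "CompoundA", 305.0, "[M+Cl]-"),
            _cand("f1", "CompoundB", 300.0, "[M+FA-H]-"),
        ]
        final = resolve_compatibility(group_adducts_by_rt(cands, CFG), CFG)
        winners = {a.feature_id: a.compound for a in final}
        assert winners["f1"] == "CompoundA"

    def test_single_candidate_unchanged(self):
        final = resolve_compatibility(group_adducts_by_rt([_cand("f1", "X", 10.0)], CFG), CFG)
        assert len(final) == 1 and final[0].compound == "X"

    def test_exact_tie_resolved_by_name_order(self):
        cands = [_cand("f1", "Zeta", 300.0), _cand("f1", "Alpha", 300.0, "[M+Cl]-")]
        final = resolve_compatibility(group_adducts_by_rt(cands, CFG), CFG)
        assert [a.compound for a in final] == ["Alpha"]

    def test_at_most_one_annotation_per_feature_and_monotone_count(self, reference_db):
        table, _ = generate(SimConfig(seed=21, mass_noise_ppm=6.0))
        cands = annotate_features(table, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG)
        grouped = group_adducts_by_rt(cands, CFG)
        final = resolve_compatibility(grouped, CFG)
        assert len(final) <= len(grouped)
        fids = [a.feature_id for a in final]
        assert len(fids) == len(set(fids))


class TestMetaboliteCounting:
    def test_empty(self):
        assert count_distinct_metabolites([]) == 0

    def test_full_recovery_counts_every_compound(self, reference_db):
        table, truth = generate(SimConfig(seed=2, dropout_p=0.0, n_contaminants=0))
        final = annotate_table(table, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG)
        assert count_distinct_metabolites(final) == truth["compound"].nunique()


class TestMsmsConfirmation:
    def test_identical_spectra_confirm(self):
        assert confirm_by_msms([263.1, 245.0, 111.0], 500.0, [263.1, 245.0, 111.0], 500.0, CFG)

    def test_one_fragment_off_by_006_fails(self):
        assert not confirm_by_msms([263.16, 245.0], 500.0, [263.10, 245.0], 500.0, CFG)

    def test_boundary_rt_29s_and_fragments_within_004_confirm(self):
        assert confirm_by_msms([263.14, 245.04], 529.0, [263.10, 245.00], 500.0, CFG)

    def test_rt_difference_at_30s_fails(self):
        assert not confirm_by_msms([263.1], 530.0, [263.1], 500.0, CFG)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            confirm_by_msms([100.0], 0.0, [], 0.0, CFG)


class TestWorkedExampleChain:
    def test_printed_formula_rows_get_their_printed_adducts(self, report_skeleton, reference_db):
        final = annotate_table(report_skeleton, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG)
        by_fid = {a.feature_id: a for a in final}
        assert by_fid["6"].compound == "Austinol intermediate (C25H30O7)"
        assert by_fid["6"].adduct == "[M-H]-"
        assert by_fid["28"].compound == "A heptaketide (C15H24O2)"
        assert by_fid["28"].adduct == "[M+Na-2H]-"

    def test_full_table_reproduced_up_to_printed_rounding(self, annotation_report, report_skeleton, reference_db):
        """With the gate widened by the half-milli-Da rounding of printed m/z,
        the chain reassigns every printed (compound, adduct) except the
        flagged emericellin monomer row."""
        wide = AnnotationConfig(ppm_tolerance=14.0)
        cands = annotate_features(report_skeleton, reference_db, EXTENDED_NEGATIVE_ADDUCTS, wide)
        cands = [c for c in cands if c.error_ppm < 10.0 + 1e6 * 0.0005 / c.observed_mz]
        final = resolve_compatibility(group_adducts_by_rt(cands, wide), wide)
        got = {a.feature_id: (a.compound, a.adduct) for a in final}
        for row in annotation_report.itertuples():
            fid = str(row.feature_id)
            if row.feature_id == 25:
                assert got.get(fid) != (row.annotation, row.adduct)
                continue
            assert got.get(fid) == (row.annotation, row.adduct)
        # emericellin itself is still recovered through its dimer row
        assert count_distinct_metabolites(final) == 19


class TestRecoveryOnSyntheticData:
    def test_two_ppm_noise_recovers_most_true_pairs(self, reference_db):
        scores = []
        for seed in range(3):
            table, truth = generate(SimConfig(seed=seed))
            final = annotate_table(table, reference_db, DEFAULT_NEGATIVE_ADDUCTS, CFG)
            s = score_annotations(final, truth)
            scores.append((s.precision, s.recall))
        assert np.mean([p for p, _ in scores]) >= 0.95
        assert np.mean([r for _, r in scores]) >= 0.95
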