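import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from _oracles import (
    friedman_permutation_p,
    friedman_reference_statistic,
    wilcoxon_exact_enumeration,
)
from octavd import (
    CohortEffectSpec,
    assign_controls,
    friedman_statistic,
    friedman_test,
    select_index_sector,
    serial_analysis,
    simulate_cohort,
    wilcoxon_signed_rank,
)
from octavd.cohort_stats import CONTROL_MAP
from octavd.types import SECTOR_ORDER


class TestControlAssignment:
    @pytest.mark.parametrize(
        "implant,expected",
        [
            ("superior_nasal", {"inferior", "temporal"}),
            ("inferior_nasal", {"superior", "temporal"}),
            ("inferior_temporal", {"superior", "nasal"}),
        ],
    )
    def test_fixed_opposing_mapping(self, implant, expected):
        assert set(assign_controls(implant)) == expected

    def test_unmapped_sector_error_lists_valid_inputs(self):
        with pytest.raises(ValueError, match="superior_nasal"):
            assign_controls("superior")

    def test_mapping_total_and_self_exclusive(self):
        for implant, controls in CONTROL_MAP.items():
            assert implant in SECTOR_ORDER
            assert len(set(controls)) == 2
            assert implant not in controls
            assert all(c in SECTOR_ORDER for c in controls)


class TestIndexSectorSelection:
    def test_argmax_of_baseline_vd(self):
        assert select_index_sector({"superior_nasal": 25.6, "nasal": 24.0}) == "superior_nasal"

    def test_exact_tie_breaks_by_canonical_order(self):
        assert select_index_sector({"nasal": 25.0, "superior_nasal": 25.0}) == "superior_nasal"

    def test_single_candidate_is_itself(self):
        assert select_index_sector({"inferior": 10.0}) == "inferior"

    def test_missing_baseline_record_rejected(self):
        with pytest.raises(ValueError, match="missing baseline"):
            select_index_sector({"nasal": 25.0}, candidates=["nasal", "superior"])


class TestWilcoxon:
    def test_five_all_positive_differences(self):
        res = wilcoxon_signed_rank(np.zeros(5), np.ones(5))
        assert res.p_value == pytest.approx(0.0625)
        assert res.n == 5
        assert res.mean_difference == pytest.approx(1.0)

    def test_symmetric_pair_is_null_centered(self):
        res = wilcoxon_signed_rank(np.array([0.0, 0.0]), np.array([2.0, -2.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_flagged(self):
        res = wilcoxon_signed_rank(np.ones(4), np.ones(4))
        assert res.p_value == 1.0
        assert res.n == 0
        assert res.n_excluded == 4

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False).map(lambda x: round(x, 1)),
            min_size=2,
            max_size=12,
        )
    )
    def test_exact_p_matches_full_enumeration(self, diffs):
        d = np.asarray(diffs, dtype=float)
        if not np.any(d != 0):
            return
        res = wilcoxon_signed_rank(np.zeros_like(d), d)
        assert res.p_value == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-12)

    def test_large_n_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(25, 3, 23)
        fup = base + rng.normal(-3, 3, 23)
        res = wilcoxon_signed_rank(base, fup)
        ref = sps.wilcoxon(fup - base, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_ci_contains_mean_difference(self):
        rng = np.random.default_rng(1)
        base = rng.normal(25, 3, 20)
        fup = base - 2 + rng.normal(0, 1, 20)
        res = wilcoxon_signed_rank(base, fup)
        lo, hi = res.ci95
        assert lo <= res.mean_difference <= hi
        assert lo < 0  # clear negative shift


class TestFriedman:
    def test_identical_values_give_null_result(self):
        m = np.tile([23.0, 23.0, 23.0], (5, 1))
        res = friedman_test(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_exact_p_matches_permutation_oracle_on_4x3(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            m = rng.normal(size=(4, 3)) + np.array([0.0, 0.4, 0.8])
            res = friedman_test(m, method="exact")
            assert res.p_value == pytest.approx(friedman_permutation_p(m), abs=1e-12)

    def test_statistic_matches_scipy_and_reference(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(10, 4))
        stat = friedman_statistic(m)
        ref = sps.friedmanchisquare(*m.T)
        assert stat == pytest.approx(ref.statistic)
        assert stat == pytest.approx(friedman_reference_statistic(m))

    def test_perfect_ordering_reaches_maximal_statistic(self):
        m = np.arange(3)[None, :] + np.zeros((10, 1))
        m = m + np.arange(10)[:, None] * 0.01  # distinct rows, same ordering
        res = friedman_test(m, method="chisq")
        assert res.statistic == pytest.approx(20.0)  # 12n/(k(k+1)) * sum dev^2
        assert res.p_value < 0.001

    def test_chisq_approximation_tracks_permutation_distribution(self):
        # the chi-square reference is mildly anti-conservative at n=20;
        # agreement tightens as n grows
        rng = np.random.default_rng(4)
        diffs = []
        for i in range(6):
            m20 = rng.normal(size=(20, 3)) + np.array([0.0, 0.3, 0.5])
            p_chi = friedman_test(m20, method="chisq").p_value
            p_perm = friedman_test(
                m20, method="sampled", n_resamples=20000, seed=i
            ).p_value
            diffs.append(abs(p_chi - p_perm))
        assert np.mean(diffs) < 0.05
        m60 = rng.normal(size=(60, 3)) + np.array([0.0, 0.2, 0.3])
        p_chi = friedman_test(m60, method="chisq").p_value
        p_perm = friedman_test(m60, method="sampled", n_resamples=40000, seed=0).p_value
        assert abs(p_chi - p_perm) < 0.02

    def test_incomplete_blocks_excluded_and_counted(self):
        m = np.random.default_rng(5).normal(size=(6, 3))
        m[1, 2] = np.nan
        res = friedman_test(m)
        assert res.n == 5
        assert res.n_excluded == 1

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((2, 3)))


class TestSerialAnalysis:
    def test_deterministic_effect_recovered_exactly(self):
        spec = CohortEffectSpec(
            between_eye_sd=0.0, measurement_sd=0.0, dropout_per_visit=(0,) * 5
        )
        cohort = simulate_cohort(spec, seed=0)
        rep = serial_analysis(cohort)
        month1 = rep.report["groups"]["implant"]["wilcoxon_vs_baseline"]["month1"]
        assert month1["mean_difference"] == pytest.approx(22.5 - 25.6)

    def test_groups_and_visits_structured_like_the_design(self):
        rep = serial_analysis(simulate_cohort(seed=1))
        assert set(rep.report["groups"]) == {"implant", "control_1", "control_2"}
        imp = rep.report["groups"]["implant"]
        assert set(imp["wilcoxon_vs_baseline"]) == {"week1", "month1", "month3", "month6"}
        assert "friedman" in imp
        assert rep.report["multiplicity_adjustment"] == "none"

    def test_pairing_stays_within_eyes(self):
        cohort = simulate_cohort(seed=2)
        rep = serial_analysis(cohort)
        for group, g in rep.report["groups"].items():
            for visit, w in g["wilcoxon_vs_baseline"].items():
                eyes_at_visit = cohort[
                    (cohort["visit"] == visit)
                ]["eye_id"].nunique()
                assert w["n"] + w.get("n_excluded", 0) <= eyes_at_visit

    def test_summary_has_table_shape(self):
        rep = serial_analysis(simulate_cohort(seed=3))
        assert {"group", "visit", "n", "mean_vd", "sd_vd", "p_value"} <= set(
            rep.summary.columns
        )
        imp = rep.summary[rep.summary["group"] == "implant"]
        assert list(imp["visit"]) == ["pre", "week1", "month1", "month3", "month6"]

    def test_missing_baseline_rejected(self):
        cohort = simulate_cohort(seed=4)
        cohort = cohort[cohort["visit"] != "pre"]
        with pytest.raises(ValueError, match="baseline"):
            serial_analysis(cohort)
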