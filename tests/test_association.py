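import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import bh_oracle, fisher_oracle, two_arm_config
from repeatrisk.association import (
    AnalysisConfig,
    build_carrier_table,
    carrier_frequency_reciprocal,
    fdr_adjust,
    fisher_exact,
    mean_comparison,
    odds_ratio,
    omnibus_exact_test,
    run_category_association,
    scan_log_or_diff,
    split_point_scan,
)
from repeatrisk.simulate import generate_cohort


class TestOddsRatio:
    def test_symmetric_table_is_one(self):
        assert odds_ratio((10, 90, 10, 90))[0] == pytest.approx(1.0)

    def test_cross_product(self):
        or_est, lo, hi = odds_ratio((20, 80, 10, 90))
        assert or_est == pytest.approx(2.25)
        assert lo < 2.25 < hi

    def test_zero_cell_haldane_anscombe(self):
        or_est, lo, hi = odds_ratio((5, 0, 2, 7))
        # (5.5 * 7.5) / (0.5 * 2.5) computed on corrected cells
        assert or_est == pytest.approx(33.0)
        se = np.sqrt(1 / 5.5 + 1 / 0.5 + 1 / 2.5 + 1 / 7.5)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(33.0 * np.exp(-z * se))
        assert hi == pytest.approx(33.0 * np.exp(z * se))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            odds_ratio((0, 0, 0, 0))

    @given(st.tuples(*[st.integers(min_value=1, max_value=60)] * 4))
    def test_group_transpose_reciprocal(self, table):
        """Swapping case and control rows inverts the OR exactly."""
        a, b, c, d = table
        direct = odds_ratio((a, b, c, d))[0]
        swapped = odds_ratio((c, d, a, b))[0]
        assert direct * swapped == pytest.approx(1.0)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact((5, 5, 5, 5)) == pytest.approx(1.0)

    def test_diagonal_three(self):
        # enumeration over tables with margins (3,3)/(3,3)
        assert fisher_exact((3, 0, 0, 3)) == pytest.approx(0.1)

    @given(st.tuples(*[st.integers(min_value=0, max_value=15)] * 4))
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        assert fisher_exact(table) == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


class TestFdr:
    def test_single_test_unchanged(self):
        assert fdr_adjust([0.04]) == pytest.approx([0.04])

    def test_worked_four_value_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_bh_definition(self, pvals):
        assert fdr_adjust(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bounded_dominating_and_rank_preserving(self, pvals):
        q = fdr_adjust(pvals)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(pvals) - 1e-12)
        # adjustment preserves the ordering of the inputs
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_sorted_inputs_give_nondecreasing_outputs(self):
        q = fdr_adjust([0.001, 0.01, 0.2, 0.5, 0.9])
        assert np.all(np.diff(q) >= 0)


class TestCarrierTable:
    def test_tiny_roster(self):
        df = pd.DataFrame(
            {
                "group": ["MDD"] * 3 + ["CON"] * 2,
                "a1": [15, 15, 15, 15, 22],
                "a2": [18, 18, 18, 22, 25],
            }
        )
        assert build_carrier_table(df, "bb", "MDD") == (3, 0, 0, 2)

    def test_hand_enumerated_roster(self):
        df = pd.DataFrame(
            {
                "group": ["MDD"] * 6 + ["CON"] * 4,
                "a1": [15, 15, 15, 15, 15, 10, 15, 15, 15, 15],
                "a2": [22, 22, 22, 22, 18, 11, 22, 18, 18, 18],
            }
        )
        assert build_carrier_table(df, "bc", "MDD") == (4, 2, 1, 3)

    @given(st.integers(min_value=0, max_value=3))
    def test_cells_sum_to_roster_size(self, seed):
        cohort = generate_cohort(two_arm_config(n_case=40, n_con=40), seed=seed)
        table = build_carrier_table(cohort, "bb", "ANX")
        assert sum(table) == len(cohort)

    def test_empty_stratum_raises(self):
        with pytest.raises(ValueError):
            build_carrier_table(pd.DataFrame(columns=["group", "a1", "a2"]), "bb", "MDD")


class TestCategoryScreen:
    def test_min_count_filter_excludes_sparse_combinations(self, null_cohort):
        screen = run_category_association(
            null_cohort, case_group="ANX", stratum="older", compute_omnibus=False
        )
        emitted = {r.combination for r in screen.results}
        for r in screen.results:
            assert r.counts[0] >= 5 and r.counts[2] >= 5
        # a combination with 4 case carriers must be absent
        forced = null_cohort.copy()
        lab = forced.apply(lambda s: (s.a1 <= 12) and (13 <= s.a2 <= 20), axis=1)
        # ab carriers among ANX cases reduced to 4 by relabelling extras as bb
        ab_cases = forced[(forced.group == "ANX") & lab].index
        for idx in ab_cases[4:]:
            forced.loc[idx, "a1"] = 15
        screen2 = run_category_association(
            forced, case_group="ANX", stratum="all", compute_omnibus=False
        )
        ab = [r for r in screen2.results if r.combination == "ab"]
        assert not ab

    def test_conservation_and_q_dominates_p(self, null_cohort):
        screen = run_category_association(
            null_cohort, case_group="ANX", stratum="older", compute_omnibus=False
        )
        n = len(null_cohort)
        for r in screen.results:
            assert sum(r.counts) == n
            assert r.q >= r.p - 1e-12
            assert r.ci_low <= r.or_estimate <= r.ci_high

    def test_null_labels_rarely_reach_significance(self, null_cohort):
        """Label permutation: q < 0.05 for any combination in < 10% of reps."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 100
        for _ in range(reps):
            perm = null_cohort.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            screen = run_category_association(
                perm, case_group="ANX", stratum="older", compute_omnibus=False
            )
            if any(r.q < 0.05 for r in screen.results):
                hits += 1
        assert hits <= 10

    def test_omnibus_p_reported(self, null_cohort):
        screen = run_category_association(null_cohort, case_group="ANX", stratum="older")
        assert 0.0 < screen.omnibus_p <= 1.0

    def test_omnibus_matches_exact_2x2(self):
        table = np.array([[8, 2], [3, 9]])
        assert omnibus_exact_test(table) == pytest.approx(
            fisher_oracle(8, 2, 3, 9), abs=1e-9
        )

    def test_omnibus_detects_gross_association(self):
        table = np.array([[50, 5], [5, 50], [20, 20]])
        assert omnibus_exact_test(table, n_resamples=999, seed=1) < 0.01


class TestSplitScan:
    def test_canonical_split_matches_direct_screen(self, null_cohort):
        scan = split_point_scan(null_cohort, case_group="ANX", stratum="older")
        direct = run_category_association(
            null_cohort, case_group="ANX", stratum="older", compute_omnibus=False
        ).to_frame()
        s21 = scan[scan.split_point == 21].set_index("combination")
        d = direct.set_index("combination")
        for comb in ("bb", "bc"):
            assert s21.loc[comb, "or"] == pytest.approx(d.loc[comb, "or"])
            assert s21.loc[comb, "p"] == pytest.approx(d.loc[comb, "p"])

    def test_scan_covers_requested_splits(self, null_cohort):
        config = AnalysisConfig(split_points=(19, 20, 21, 22, 23))
        scan = split_point_scan(
            null_cohort, config=config, case_group="ANX", stratum="older"
        )
        assert set(scan.split_point) == {19, 20, 21, 22, 23}
        diffs = scan_log_or_diff(scan)
        assert len(diffs) == 5


class TestMeanComparison:
    def test_duplicated_groups_give_zero_f(self, null_cohort):
        twin = null_cohort.copy()
        twin["group"] = np.where(twin["group"] == "ANX", "CON", "ANX")
        both = pd.concat([null_cohort, twin], ignore_index=True)
        res = mean_comparison(both, case_group="ANX")
        assert (res["F"] < 1e-10).all()

    def test_planted_shift_detected(self):
        cohort = generate_cohort(two_arm_config(n_case=500, n_con=500), seed=9)
        shifted = cohort.copy()
        mask = shifted["group"] == "ANX"
        shifted.loc[mask, "a1"] += 1
        shifted.loc[mask, "a2"] += 1
        res = mean_comparison(shifted, case_group="ANX", covariates=("age", "sex"))
        assert (res["p"] < 0.001).all()

    def test_null_p_uniform(self):
        """ANOVA p under the null is uniform across seeded replicates."""
        pvals = []
        for seed in range(150):
            cohort = generate_cohort(two_arm_config(n_case=120, n_con=120), seed=seed)
            res = mean_comparison(cohort, case_group="ANX")
            pvals.append(res.loc[res.allele == "A1", "p"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_group_raises(self, null_cohort):
        with pytest.raises(ValueError):
            mean_comparison(null_cohort[null_cohort.group == "CON"], case_group="ANX")


def test_carrier_frequency_reciprocal_half_up():
    assert carrier_frequency_reciprocal(2, 2629) == 1315
    assert carrier_frequency_reciprocal(3, 1566) == 522
    with pytest.raises(ValueError):
        carrier_frequency_reciprocal(0, 100)
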