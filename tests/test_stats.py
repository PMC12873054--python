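"""Exact nonparametric tests: worked examples, enumeration oracles, properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import renalperf as rp
from renalperf.stats import (
    HodgesLehmannResult,
    exact_mann_whitney,
    exact_wilcoxon_signed_rank,
    hodges_lehmann,
    hodges_lehmann_paired,
    mann_whitney_critical_u,
    mann_whitney_null_pmf,
    rank_biserial_paired,
    rank_biserial_unpaired,
    signed_rank_null_pmf,
)


class TestMannWhitney:
    def test_complete_separation_of_five_vs_five(self):
        res = exact_mann_whitney(range(1, 6), range(6, 11))
        assert res.p_value == pytest.approx(2 / 252)
        assert round(res.p_value, 3) == 0.008

    def test_single_observations_give_p_one(self):
        assert exact_mann_whitney([1.0], [2.0]).p_value == 1.0

    def test_interleaved_pairs_by_enumeration(self):
        # all 6 assignments of {1,2,3,4} into two pairs: 4 of 6 are as or
        # more extreme than the observed split {1,3} vs {2,4}
        assert exact_mann_whitney([1, 3], [2, 4]).p_value == pytest.approx(2 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            exact_mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 2), (5, 5), (4, 6)])
    def test_null_pmf_matches_full_enumeration(self, n1, n2):
        pmf = mann_whitney_null_pmf(n1, n2)
        counts = np.zeros(n1 * n2 + 1)
        for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
            u = sum(combo) - n1 * (n1 + 1) // 2
            counts[u] += 1
        np.testing.assert_allclose(pmf, counts / counts.sum(), atol=1e-15)

    @pytest.mark.parametrize("n1, n2", [(1, 1), (6, 6), (5, 7), (10, 10), (12, 8)])
    def test_null_pmf_sums_to_one(self, n1, n2):
        assert mann_whitney_null_pmf(n1, n2).sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.standard_normal(rng.integers(2, 9))
            b = rng.standard_normal(rng.integers(2, 9)) + rng.normal()
            ours = exact_mann_whitney(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_p_values_are_valid_under_the_null(self):
        # exact-test conservatism: P(p <= alpha) <= alpha over the full
        # enumeration of group assignments of untied data at n1 = n2 = 5
        values = np.arange(1, 11, dtype=float)
        p_values = []
        for combo in itertools.combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(combo)] = True
            p_values.append(exact_mann_whitney(values[mask], values[~mask]).p_value)
        p_values = np.asarray(p_values)
        for alpha in np.unique(p_values):
            assert np.mean(p_values <= alpha) <= alpha + 1e-12


class TestWilcoxonSignedRank:
    @pytest.mark.parametrize(
        "diffs, expected_p",
        [
            ([1, 2, 3, 4], 2 / 16),
            ([1, 2, 3], 2 / 8),
            ([1, 2, -3, 4, 5], 10 / 32),
        ],
    )
    def test_worked_examples(self, diffs, expected_p):
        assert exact_wilcoxon_signed_rank(diffs).p_value == pytest.approx(expected_p)

    def test_statistic_is_smaller_rank_sum(self):
        res = exact_wilcoxon_signed_rank([1, 2, -3, 4, 5])
        assert res.statistic == 3.0

    def test_zero_differences_dropped(self):
        with_zeros = exact_wilcoxon_signed_rank([0.0, 1, 2, 3, 0.0])
        without = exact_wilcoxon_signed_rank([1, 2, 3])
        assert with_zeros.p_value == without.p_value

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            exact_wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize(
        "ranks",
        [np.arange(1, 6), np.arange(1, 13), np.array([1.5, 1.5, 3.0, 4.5, 4.5])],
    )
    def test_null_pmf_matches_sign_enumeration(self, ranks):
        support, pmf = signed_rank_null_pmf(ranks)
        counts = {}
        n = len(ranks)
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(r for r, s in zip(ranks, signs) if s)
            counts[w] = counts.get(w, 0) + 1
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        for w, c in counts.items():
            idx = np.nonzero(np.isclose(support, w))[0]
            assert pmf[idx].sum() == pytest.approx(c / 2**n)

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            d = rng.standard_normal(rng.integers(3, 10)) + 0.3
            ours = exact_wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, mode="exact", alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestRankBiserial:
    def test_complete_separation_gives_unit_effect(self):
        assert rank_biserial_unpaired(range(6, 11), range(1, 6)) == 1.0

    def test_five_of_twentyfive_favorable(self):
        assert rank_biserial_unpaired([1, 2, 3, 4, 10], [5, 6, 7, 8, 9]) == -0.6

    def test_identical_samples_give_zero(self):
        assert rank_biserial_unpaired([1, 2, 3], [1, 2, 3]) == 0.0

    def test_paired_all_positive(self):
        assert rank_biserial_paired([0.5, 1.2, 2.0, 3.1]) == 1.0

    def test_paired_rank_three_negative(self):
        assert rank_biserial_paired([1, 2, -3, 4, 5]) == pytest.approx((12 - 3) / 15)

    @given(
        a=st.lists(st.integers(0, 50), min_size=2, max_size=8),
        b=st.lists(st.integers(0, 50), min_size=2, max_size=8),
    )
    def test_bounded_and_consistent_with_u_statistic(self, a, b):
        r = rank_biserial_unpaired(a, b)
        assert -1.0 <= r <= 1.0
        if len(set(a) | set(b)) == len(a) + len(b):  # ties-free
            u_b = exact_mann_whitney(a, b).statistic  # pairs favoring b
            assert r == pytest.approx(1.0 - 2.0 * u_b / (len(a) * len(b)))

    @given(d=st.lists(st.integers(-20, 20).filter(bool), min_size=1, max_size=10))
    def test_paired_effect_bounded(self, d):
        assert -1.0 <= rank_biserial_paired(d) <= 1.0


class TestHodgesLehmann:
    def test_pure_shift_recovered(self):
        a = np.array([3.1, 4.0, 5.5, 7.2, 9.9])
        c = 1.7
        res = hodges_lehmann(a + c, a)
        assert res.estimate == pytest.approx(c)

    def test_small_example_by_enumeration(self):
        res = hodges_lehmann([2, 3, 4], [1, 2, 3])
        assert res.estimate == 1.0  # median of {-1,0,0,1,1,1,2,2,3}

    def test_critical_value_at_five_vs_five(self):
        # 2 * P(U <= 2) = 8/252 <= 0.05 < 2 * P(U <= 3)
        assert mann_whitney_critical_u(5, 5) == 2

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(6)
        b = rng.standard_normal(5)
        base = hodges_lehmann(a, b)
        moved = hodges_lehmann(a + 2.5, b)
        assert moved.estimate == pytest.approx(base.estimate + 2.5)
        assert moved.ci_low == pytest.approx(base.ci_low + 2.5)
        assert moved.ci_high == pytest.approx(base.ci_high + 2.5)

    def test_unattainable_coverage_flagged_widest(self):
        res = hodges_lehmann([1.0, 2.0], [0.5, 1.5])
        assert res.widest_attainable
        assert res.ci_low <= res.estimate <= res.ci_high

    @given(
        a=st.lists(
            st.floats(-50, 50, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=3,
            max_size=8,
            unique=True,
        ),
        b=st.lists(
            st.floats(-50, 50, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=3,
            max_size=8,
            unique=True,
        ),
    )
    def test_matches_bruteforce_pairwise_enumeration(self, a, b):
        res = hodges_lehmann(a, b)
        diffs = sorted(x - y for x in a for y in b)
        assert res.estimate == pytest.approx(np.median(diffs))
        # CI bounds are order statistics of the pairwise differences
        u_crit = mann_whitney_critical_u(len(a), len(b))
        if u_crit is None:
            assert res.ci_low == diffs[0] and res.ci_high == diffs[-1]
        else:
            assert res.ci_low == pytest.approx(diffs[u_crit])
            assert res.ci_high == pytest.approx(diffs[-(u_crit + 1)])

    def test_paired_walsh_average_estimate(self):
        d = np.array([1.0, 2.0, 4.0])
        res = hodges_lehmann_paired(d)
        walsh = sorted([1.0, 1.5, 2.0, 2.5, 3.0, 4.0])
        assert res.estimate == pytest.approx(np.median(walsh))

    def test_paired_equivariance(self):
        d = np.array([0.4, 1.1, -0.3, 2.2, 0.9, 1.5])
        base = hodges_lehmann_paired(d)
        moved = hodges_lehmann_paired(d + 1.0)
        assert moved.estimate == pytest.approx(base.estimate + 1.0)
        assert moved.ci_low == pytest.approx(base.ci_low + 1.0)


def _summary_table(k16, k30, v16=None, v30=None, native=None):
    rows = []
    for group, ks, vs in (("16h", k16, v16), ("30min", k30, v30)):
        for i, k in enumerate(ks):
            rows.append(
                {
                    "animal_id": f"{group}_{i}",
                    "group": group,
                    "roi_label": "transplant",
                    "median_ktrans": k,
                    "median_vp": vs[i] if vs is not None else 20.0 + i,
                }
            )
            if native is not None and i < native:
                for lab in ("left_native", "right_native"):
                    rows.append(
                        {
                            "animal_id": f"{group}_{i}",
                            "group": group,
                            "roi_label": lab,
                            "median_ktrans": k * 0.5 + 0.01 * i,
                            "median_vp": 30.0 + i,
                        }
                    )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_give_p_one_and_zero_effect(self):
        table = _summary_table([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        res = rp.compare_groups(table, "unpaired", "median_ktrans")
        assert res.p_two_sided == 1.0
        assert res.effect_size == 0.0

    def test_direction_is_first_group_minus_second(self):
        table = _summary_table([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        res = rp.compare_groups(table, "unpaired", "median_ktrans")
        assert res.effect_size == 1.0
        assert res.hl_estimate == pytest.approx(5.0)
        assert res.p_two_sided == pytest.approx(2 / 252)

    def test_paired_drops_incomplete_animals(self):
        table = _summary_table([2, 3, 4, 5, 6], [1, 2, 3, 4, 5], native=3)
        res = rp.compare_groups(
            table, "paired", "median_ktrans", group="16h", native_roi="left_native"
        )
        assert res.n1 == 3  # only animals 0..2 have native rows

    def test_too_few_observations_rejected(self):
        table = _summary_table([1.0], [2.0])
        with pytest.raises(ValueError):
            rp.compare_groups(table, "unpaired", "median_ktrans")

    def test_full_report_layout(self):
        table = _summary_table([2, 3, 4, 5, 6], [1, 2, 3, 4, 5], native=5)
        report = rp.full_report(table)
        assert set(report["design"]) == {"unpaired", "paired"}
        # 2 parameters x (1 intergroup + 4 intragroup) comparisons
        assert len(report) == 10
        assert {"p_two_sided", "effect_size", "hl_ci_low", "hl_ci_high"} <= set(
            report.columns
        )

    def test_power_at_study_medians(self):
        # the exact U test at n = 5/5 detects the configured transplant
        # ktrans separation in >= 90% of replicates
        cfg = rp.PhantomConfig()
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            k16 = [rp.draw_animal_params(cfg, "16h", rng)["transplant"][0] for _ in range(5)]
            k30 = [rp.draw_animal_params(cfg, "30min", rng)["transplant"][0] for _ in range(5)]
            res = rp.compare_unpaired(np.array(k16), np.array(k30))
            hits += res.p_two_sided <= 0.05
        assert hits >= 90
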