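"""Paired-agreement statistics against hand calculations and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from drusenkit.agreement import (
    PairedMeasures,
    bland_altman,
    icc_two_way,
    jonckheere_terpstra,
    kappa_high_risk,
    paired_rmse,
    wilcoxon_signed_rank,
)


class TestIcc:
    def test_identical_methods_give_one(self):
        a = np.array([0.1, 0.2, 0.3, 0.5])
        assert icc_two_way((a, a), "consistency").estimate == pytest.approx(1.0)
        assert icc_two_way((a, a), "agreement").estimate == pytest.approx(1.0)

    def test_hand_anova_example(self):
        # a={1,2,3}, b={2,3,4}: MSR=2, MSC=1.5, MSE=0
        a, b = [1, 2, 3], [2, 3, 4]
        assert icc_two_way((a, b), "consistency").estimate == pytest.approx(1.0)
        assert icc_two_way((a, b), "agreement").estimate == pytest.approx(2 / 3)

    def test_matches_pingouin_reference_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        a = rng.normal(10, 2, 50)
        b = 0.8 * a + rng.normal(0, 1, 50) + 1
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(50), 2),
                "raters": np.tile(["x", "y"], 50),
                "ratings": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        mine_c = icc_two_way((a, b), "consistency")
        mine_a = icc_two_way((a, b), "agreement")
        assert mine_c.estimate == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)
        assert mine_a.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        # pingouin prints CIs rounded to 2 decimals
        np.testing.assert_allclose(
            [round(mine_c.ci_low, 2), round(mine_c.ci_high, 2)],
            ref.loc["ICC(C,1)", "CI95"], atol=0.011,
        )
        np.testing.assert_allclose(
            [round(mine_a.ci_low, 2), round(mine_a.ci_high, 2)],
            ref.loc["ICC(A,1)", "CI95"], atol=0.011,
        )

    def test_offset_law(self):
        """A constant between-method offset leaves consistency untouched and
        strictly lowers agreement — the core of the two-flavor comparison."""
        rng = np.random.default_rng(1)
        a = rng.gamma(2, 0.05, 40)
        b = a + rng.normal(0, 0.01, 40)
        base_c = icc_two_way((a, b), "consistency")
        base_a = icc_two_way((a, b), "agreement")
        shifted = b + 0.05
        assert icc_two_way((a, shifted), "consistency").estimate == pytest.approx(
            base_c.estimate, abs=1e-9
        )
        assert icc_two_way((a, shifted), "agreement").estimate < base_a.estimate
        assert bland_altman((a, shifted)).mean_diff == pytest.approx(
            bland_altman((a, b)).mean_diff - 0.05
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_agreement_never_exceeds_consistency(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1, 0.5, 12)
        b = a * rng.uniform(0.5, 1.5) + rng.normal(0, 0.3, 12) + rng.uniform(-1, 1)
        c = icc_two_way((a, b), "consistency")
        g = icc_two_way((a, b), "agreement")
        if c.status == "ok" and g.status == "ok":
            assert g.estimate <= c.estimate + 1e-12

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.1, 0.05, 30).clip(0)
        b = a + rng.normal(0, 0.02, 30)
        for kind in ("consistency", "agreement"):
            r = icc_two_way((a, b), kind)
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_zero_between_subject_variance_undefined(self):
        a = np.full(5, 2.0)
        r = icc_two_way((a, a), "consistency")
        assert r.status == "undefined_low_variance"
        assert np.isnan(r.estimate)

    def test_requires_three_eyes(self):
        with pytest.raises(ValueError):
            icc_two_way(([1, 2], [1, 2]), "consistency")


class TestBlandAltman:
    def test_constant_offset(self):
        b = np.array([0.1, 0.4, 0.2])
        r = bland_altman((b + 0.01, b))
        assert r.mean_diff == pytest.approx(0.01)
        assert r.sd_diff == pytest.approx(0.0)
        assert (r.loa_low, r.loa_high) == (pytest.approx(0.01), pytest.approx(0.01))

    def test_hand_example(self):
        r = bland_altman(([2.0, 3.0], [1.0, 2.0]))
        assert r.mean_diff == pytest.approx(1.0)
        assert r.standardized_mean_diff == pytest.approx(0.5)  # mean avg = 2

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        fwd, rev = bland_altman((a, b)), bland_altman((b, a))
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert abs(rev.standardized_mean_diff) == pytest.approx(
            abs(fwd.standardized_mean_diff)
        )

    def test_all_zero_averages_flagged(self):
        r = bland_altman(([0.0, 0.0], [0.0, 0.0]))
        assert r.status == "undefined_zero_mean"


class TestRmse:
    def test_identical_is_zero(self):
        assert paired_rmse(([1.0, 2.0], [1.0, 2.0])) == 0.0

    def test_hand_value(self):
        assert paired_rmse(([0.0, 3.0], [0.0, 0.0])) == pytest.approx(np.sqrt(4.5))

    def test_rmse_at_least_abs_mean_diff(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.uniform(0, 1, 15), rng.uniform(0, 1, 15)
            assert paired_rmse((a, b)) >= abs(bland_altman((a, b)).mean_diff) - 1e-12


class TestWilcoxon:
    def test_six_positive_differences_exact(self):
        r = wilcoxon_signed_rank((np.arange(1.0, 7.0), np.zeros(6)))
        assert r.exact
        assert r.p_value == pytest.approx(2 / 64)

    def test_antisymmetric_pair(self):
        r = wilcoxon_signed_rank(([2.0, 0.0], [1.0, 1.0]))  # diffs {+1, -1}
        assert r.p_value == pytest.approx(1.0)

    def test_all_zero_differences_flagged(self):
        r = wilcoxon_signed_rank(([1.0, 1.0], [1.0, 1.0]))
        assert r.status == "all_zero" and r.p_value == 1.0

    def test_exact_and_normal_agree_at_crossover(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.2, 1, 25)
        z = np.zeros(25)
        p_exact = wilcoxon_signed_rank((np.abs(x) + x, np.abs(x)), exact_max_n=25)
        p_norm = wilcoxon_signed_rank((np.abs(x) + x, np.abs(x)), exact_max_n=0)
        assert abs(p_exact.p_value - p_norm.p_value) < 0.01

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(5, 1, 18))
        y = x - rng.normal(0.3, 1, 18)
        mine = wilcoxon_signed_rank((x, y))
        ref = stats.wilcoxon(x, y, mode="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestJonckheere:
    def test_perfectly_separated_triples(self):
        r = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == 12  # the maximum
        assert r.exact
        assert r.p_value == pytest.approx(1 / 90)

    def test_identical_constant_groups(self):
        r = jonckheere_terpstra([[2.0, 2, 2], [2, 2, 2], [2, 2, 2]])
        assert r.statistic == pytest.approx(13.5)  # half of the 27 pair maximum
        assert r.p_value == 1.0  # every arrangement yields the same J

    def test_reversal_antisymmetry(self):
        groups = [[1.0, 5, 3], [4.0, 2], [7.0, 5, 8]]
        fwd = jonckheere_terpstra(groups)
        rev = jonckheere_terpstra(groups[::-1])
        n = [len(g) for g in groups]
        max_j = sum(n[i] * n[j] for i in range(3) for j in range(i + 1, 3))
        assert rev.statistic == pytest.approx(max_j - fwd.statistic)

    def test_exact_and_normal_agree(self):
        groups = [[1.0, 5, 3], [4.0, 2, 6], [7.0, 5, 8]]
        exact = jonckheere_terpstra(groups, exact_max_n=10)
        approx = jonckheere_terpstra(groups, exact_max_n=0)
        assert abs(exact.p_value - approx.p_value) < 0.01

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2, 3]])


class TestKappa:
    def test_identical_classifications(self):
        a = np.array([0.0, 0.1, 0.2, 0.0])
        r = kappa_high_risk((a, a), 0.05, 0.05)
        assert r.kappa == pytest.approx(1.0)
        assert r.percent_agreement == 100.0

    def test_hand_2x2_table(self):
        # cells a=40, b=5, c=5, d=50: po=0.9, pe=0.505, kappa~0.798
        a = np.r_[np.ones(40), np.ones(5), np.zeros(5), np.zeros(50)]
        b = np.r_[np.ones(40), np.zeros(5), np.ones(5), np.zeros(50)]
        r = kappa_high_risk((a, b), 0.5, 0.5)
        assert r.kappa == pytest.approx((0.9 - 0.505) / (1 - 0.505))
        assert r.percent_agreement == pytest.approx(90.0)

    def test_independent_classifications_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.random(4000)
        b = rng.random(4000)
        r = kappa_high_risk((a, b), 0.5, 0.5)
        assert abs(r.kappa) < 0.05

    def test_degenerate_table_flagged(self):
        a = np.full(10, 1.0)
        r = kappa_high_risk((a, a), 0.5, 0.5)
        assert r.status == "undefined_degenerate"


def test_paired_measures_validation():
    with pytest.raises(ValueError):
        PairedMeasures(value_a=[0.1, np.nan], value_b=[0.1, 0.2])
    with pytest.raises(ValueError):
        PairedMeasures(value_a=[-0.1], value_b=[0.1])
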