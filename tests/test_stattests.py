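"""Statistical primitives against hand computations and independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from propcontest.stattests import (
    bonferroni_adjust,
    fisher_exact,
    individual_overbidding,
    kruskal_wallis,
    levene_test,
    mann_whitney,
    one_sample_t,
    oneway_anova,
    overbidding_rate,
    silverman_bandwidth,
    silverman_kde,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def anova_oracle(groups):
    """F from explicit between/within sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, allv.size - len(groups)
    return (ssb / dfb) / (ssw / dfw), (dfb, dfw)


def fisher_oracle(table):
    """Two-sided p by full hypergeometric enumeration (point-probability rule)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)

    def prob(k):
        return comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# Overbidding statistics
# ---------------------------------------------------------------------------


class TestOverbidding:
    @pytest.mark.parametrize(
        "mean, expected",
        [(26.490, 0.3245), (20.0, 0.0), (29.515, 0.47575), (15.0, -0.25)],
    )
    def test_rate(self, mean, expected):
        assert overbidding_rate(mean, 20.0) == pytest.approx(expected)

    def test_rate_requires_positive_equilibrium(self):
        with pytest.raises(ValueError):
            overbidding_rate(25.0, 0.0)

    @pytest.mark.parametrize("bid, expected", [(26, 6), (20, 0), (1, -19)])
    def test_individual_overbidding(self, bid, expected):
        assert individual_overbidding(bid, 20.0) == expected


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------


class TestOneSampleT:
    def test_printed_summary_values(self):
        r = one_sample_t(summary=(29.515, 10.446, 600), mu0=20.0)
        assert r.statistic == pytest.approx(22.312, abs=0.01)
        assert r.df == 599

    def test_raw_and_summary_agree_exactly(self, rng):
        x = rng.normal(25, 8, size=40)
        raw = one_sample_t(values=x, mu0=20.0)
        summ = one_sample_t(summary=(x.mean(), x.std(ddof=1), x.size), mu0=20.0)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-10)

    def test_matches_scipy(self, rng):
        x = rng.normal(22, 5, size=30)
        r = one_sample_t(values=x, mu0=20.0)
        t, p = sps.ttest_1samp(x, 20.0)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_zero_t_at_own_mean(self):
        assert one_sample_t(summary=(30.0, 4.0, 50), mu0=30.0).statistic == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(values=[1.0], mu0=0.0)


class TestTwoSampleT:
    def test_hand_computed_example(self):
        r = two_sample_t([1, 2, 3], [2, 3, 4])
        assert r.statistic == pytest.approx(-np.sqrt(3.0 / 2.0), abs=1e-10)
        assert r.df == 4

    def test_identical_groups_give_zero(self):
        r = two_sample_t([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.statistic == pytest.approx(0.0)

    def test_df_convention_at_design_size(self, rng):
        r = two_sample_t(rng.normal(size=20), rng.normal(size=20))
        assert r.df == 38


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------


class TestOnewayAnova:
    def test_hand_computed_example(self):
        r = oneway_anova([(1, 2, 3), (2, 3, 4), (3, 4, 5)])
        assert r.statistic == pytest.approx(3.0)
        assert r.df == (2, 6)

    def test_equal_means_give_zero(self):
        r = oneway_anova([(1, 3), (2, 2), (0, 4)])
        assert r.statistic == pytest.approx(0.0)

    @pytest.mark.parametrize("sizes", [(20, 20, 20), (600, 600, 600), (5, 9, 14)])
    def test_matches_sums_of_squares_oracle(self, sizes, rng):
        groups = [rng.normal(loc=i, size=n) for i, n in enumerate(sizes)]
        r = oneway_anova(groups)
        f, df = anova_oracle(groups)
        assert r.statistic == pytest.approx(f, rel=1e-10)
        assert r.df == df

    def test_constant_input_error_flagged(self):
        r = oneway_anova([(2.0, 2.0), (2.0, 2.0)])
        assert not r.ok


class TestBonferroni:
    @pytest.mark.parametrize(
        "ps, expected",
        [
            ((0.01, 0.02, 0.5), [0.03, 0.06, 1.0]),
            ((0.0,), [0.0]),
            ((0.4, 0.4, 0.4), [1.0, 1.0, 1.0]),
        ],
    )
    def test_examples(self, ps, expected):
        assert bonferroni_adjust(ps) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])


class TestLevene:
    def test_identical_groups_give_zero(self):
        r = levene_test([(1, 2, 3), (1, 2, 3)])
        assert r.statistic == pytest.approx(0.0)

    def test_equals_anova_on_absolute_deviations(self, rng):
        groups = [rng.normal(0, s, size=15) for s in (1.0, 2.5, 4.0)]
        r = levene_test(groups)
        devs = [np.abs(np.asarray(g) - np.mean(g)) for g in groups]
        f, df = anova_oracle(devs)
        assert r.statistic == pytest.approx(f, rel=1e-10)
        assert r.df == df

    def test_detects_scale_inflation(self, rng):
        base = rng.normal(size=30)
        r_same = levene_test([base, base + 1.0])
        r_scaled = levene_test([base, base * 10])
        assert r_scaled.statistic > r_same.statistic


class TestKruskalWallis:
    def test_hand_computed_rank_example(self):
        r = kruskal_wallis([(1, 2), (3, 4), (5, 6)])
        assert r.statistic == pytest.approx(32.0 / 7.0)
        assert r.df == 2

    @given(
        st.lists(
            st.lists(
                st.floats(0, 80, allow_nan=False).map(lambda v: round(v, 6)),
                min_size=3,
                max_size=8,
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_invariant_under_monotone_transform(self, groups):
        # values rounded to 1e-6 so exp() cannot collapse distinct inputs
        flat = [v for g in groups for v in g]
        if np.ptp(flat) == 0:
            return
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis([[math.exp(v / 40.0) for v in g] for g in groups])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_all_tied_error_flagged(self):
        assert not kruskal_wallis([(1.0, 1.0), (1.0, 1.0)]).ok

    def test_two_group_h_equals_squared_mw_z_without_corrections(self, rng):
        a, b = rng.normal(size=12), rng.normal(1.0, size=15)
        h = kruskal_wallis([a, b]).statistic
        z = mann_whitney(a, b, continuity=False).extras["z"]
        assert h == pytest.approx(z**2, rel=1e-9)


class TestMannWhitney:
    def test_identical_samples_near_zero_z(self, rng):
        x = rng.normal(size=25)
        r = mann_whitney(x, x.copy())
        assert abs(r.extras["z"]) < 1e-9
        assert r.p_value == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        r = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.extras["z"] < 0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=18), rng.normal(0.8, size=22)
        z_ab = mann_whitney(a, b).extras["z"]
        z_ba = mann_whitney(b, a).extras["z"]
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_p_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.5, size=35)
        r = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[4, 2], [4, 2]], 1.0),
            ([[0, 5], [5, 0]], 2 / 252),
        ],
    )
    def test_enumeration_examples(self, table, expected):
        assert fisher_exact(table).p_value == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_oracle_over_small_margins(self):
        cells = [0, 1, 2, 4, 7, 11]
        for a, b, c, d in itertools.product(cells, repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = fisher_exact([[a, b], [c, d]]).p_value
            assert p == pytest.approx(fisher_oracle([[a, b], [c, d]]), abs=1e-9)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestSilvermanKDE:
    def test_bandwidth_formula_with_unit_sd(self, rng):
        x = rng.normal(size=600)
        x = (x - x.mean()) / x.std(ddof=1)  # SD exactly 1, IQR > 1.34 w.h.p.
        h = silverman_bandwidth(x)
        assert h == pytest.approx(0.9 * 600 ** (-0.2), abs=1e-3)

    def test_iqr_branch(self):
        # heavy-tailed: IQR/1.34 < SD, so the IQR term governs
        x = np.concatenate([np.zeros(50) + np.linspace(-0.5, 0.5, 50), [50.0, -50.0]])
        h = silverman_bandwidth(x)
        q75, q25 = np.percentile(x, [75, 25])
        assert h == pytest.approx(0.9 * (q75 - q25) / 1.34 * x.size ** (-0.2))

    def test_density_integrates_to_one(self, rng):
        x = np.clip(rng.normal(30, 8, size=400), 0, 80)
        curve = silverman_kde(x, bounds=(-40.0, 120.0), n_grid=801)
        assert curve.integral() == pytest.approx(1.0, abs=0.01)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            silverman_kde(np.full(10, 20.0))

    def test_anodal_cohort_density_is_bimodal(self, default_cohort):
        """Equilibrium spike plus an above-equilibrium bulge, as in the
        experiment's anodal condition."""
        bids = default_cohort.loc[default_cohort["condition"] == "anodal", "bid"]
        curve = silverman_kde(bids.to_numpy())
        modes = curve.modes()
        assert any(abs(m - 20.0) <= 2.0 for m in modes)
        assert any(m > 22.0 for m in modes)
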