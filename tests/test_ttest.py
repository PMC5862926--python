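"""JZS t-test: oracles, cross-checks, invariances."""

import math

import numpy as np
import pytest
from scipy import stats

import defaultbf as d
from defaultbf.ttest import TTestSufficientStats, pooled_t


def riemann_bf10(t, n1, n2, r, lo=-15.0, hi=15.0, points=40_001):
    """Dense trapezoid-grid oracle for the two-sided JZS Bayes factor."""
    df = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    delta = np.linspace(lo, hi, points)
    integrand = (stats.nct.pdf(t, df, delta * math.sqrt(neff))
                 * stats.cauchy.pdf(delta, scale=r))
    num = np.trapezoid(integrand, delta)
    return num / stats.t.pdf(t, df)


class TestBayesFactor:
    def test_matches_dense_grid_oracle(self):
        stats_ = TTestSufficientStats(2.0, 20, 20)
        mine = d.jzs_ttest_bf(stats_, d.EffectSizePrior("cauchy", d.SQRT2_OVER_2))
        oracle = riemann_bf10(2.0, 20, 20, d.SQRT2_OVER_2)
        assert mine.bf10 == pytest.approx(oracle, rel=1e-4)

    @pytest.mark.parametrize("t,n1,n2,r", [
        (2.0, 20, 20, 0.707), (-1.1, 48, 54, 1.0),
        (0.0, 10, 12, 0.707), (4.5, 30, 25, 1.414),
    ])
    def test_matches_closed_form_reference(self, t, n1, n2, r):
        """Independent closed-form implementation agrees to 4 decimals."""
        pingouin = pytest.importorskip("pingouin")
        mine = d.jzs_ttest_bf(TTestSufficientStats(t, n1, n2),
                              d.EffectSizePrior("cauchy", r))
        ref = float(pingouin.bayesfactor_ttest(t, n1, n2, r=r))
        assert mine.bf10 == pytest.approx(ref, rel=1e-4)

    def test_vanishing_scale_gives_bf_one(self):
        stats_ = TTestSufficientStats(2.0, 20, 20)
        for r in (1e-4, 1e-6):
            bf = d.jzs_ttest_bf(stats_, d.EffectSizePrior("cauchy", r))
            assert bf.bf10 == pytest.approx(1.0, abs=5e-3 if r > 1e-5 else 1e-4)

    def test_two_sided_symmetric_in_t(self):
        prior = d.EffectSizePrior()
        for t in (0.5, 1.7, 3.2):
            a = d.jzs_ttest_bf(TTestSufficientStats(t, 15, 18), prior)
            b = d.jzs_ttest_bf(TTestSufficientStats(-t, 15, 18), prior)
            assert a.log_bf10 == pytest.approx(b.log_bf10, abs=1e-8)

    def test_one_sided_mirror(self):
        pos = d.EffectSizePrior("folded_cauchy_positive")
        neg = d.EffectSizePrior("folded_cauchy_negative")
        for t in (-2.1, 0.3, 1.8):
            a = d.jzs_ttest_bf(TTestSufficientStats(t, 25, 20), pos)
            b = d.jzs_ttest_bf(TTestSufficientStats(-t, 25, 20), neg)
            assert a.log_bf10 == pytest.approx(b.log_bf10, abs=1e-7)

    def test_mixture_identity(self, rng):
        """BF10 = (BF+0 + BF-0)/2 for the symmetric two-sided prior."""
        for _ in range(50):
            t = rng.normal(0, 2)
            n1, n2 = rng.integers(5, 80, size=2)
            r = rng.uniform(0.3, 1.5)
            stats_ = TTestSufficientStats(float(t), int(n1), int(n2))
            two = d.jzs_ttest_bf(stats_, d.EffectSizePrior("cauchy", r)).bf10
            pos = d.jzs_ttest_bf(stats_, d.EffectSizePrior("folded_cauchy_positive", r)).bf10
            neg = d.jzs_ttest_bf(stats_, d.EffectSizePrior("folded_cauchy_negative", r)).bf10
            assert two == pytest.approx(0.5 * (pos + neg), rel=1e-8)

    def test_monotone_in_abs_t(self):
        prior = d.EffectSizePrior()
        bfs = [d.jzs_ttest_bf(TTestSufficientStats(t, 20, 20), prior).bf10
               for t in np.linspace(0, 5, 11)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_bf10_bf01_reciprocal(self):
        bf = d.jzs_ttest_bf(TTestSufficientStats(1.3, 12, 14))
        assert bf.bf10 * bf.bf01 == pytest.approx(1.0, rel=1e-15)

    def test_invalid_stats_rejected(self):
        with pytest.raises(ValueError):
            TTestSufficientStats(float("nan"), 10, 10)
        with pytest.raises(ValueError):
            TTestSufficientStats(1.0, 1, 10)
        with pytest.raises(ValueError):
            TTestSufficientStats(1.0, 1)


class TestPosterior:
    def test_median_zero_at_t_zero(self):
        post = d.posterior_delta(TTestSufficientStats(0.0, 20, 20))
        assert post.median == pytest.approx(0.0, abs=1e-6)

    def test_quantiles_match_grid_oracle(self):
        t, n1, n2 = 1.5, 30, 30
        post = d.posterior_delta(TTestSufficientStats(t, n1, n2))
        # independent cumulative-sum oracle on a dense grid
        df, neff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
        delta = np.linspace(-4, 4, 200_001)
        dens = (stats.nct.pdf(t, df, delta * math.sqrt(neff))
                * stats.cauchy.pdf(delta, scale=d.SQRT2_OVER_2))
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        for q, target in ((post.ci95[0], 0.025), (post.median, 0.5),
                          (post.ci95[1], 0.975)):
            oracle = float(np.interp(target, cdf, delta))
            assert q == pytest.approx(oracle, abs=1e-3)

    def test_one_sided_posterior_truncated(self):
        prior = d.EffectSizePrior("folded_cauchy_positive")
        post = d.posterior_delta(TTestSufficientStats(-1.0, 25, 25), prior)
        assert post.ci95[0] >= 0.0
        assert post.median >= 0.0

    def test_interval_contains_95_percent(self):
        stats_ = TTestSufficientStats(2.2, 18, 22)
        post = d.posterior_delta(stats_)
        assert post.ci95[0] <= post.median <= post.ci95[1]


class TestSavageDickey:
    def test_agrees_with_integral_bf(self):
        """Two independent routes: marginal-likelihood ratio vs density ratio."""
        prior = d.EffectSizePrior()
        for t, n in ((2.0, 20), (0.4, 35), (-1.2, 50)):
            stats_ = TTestSufficientStats(t, n, n)
            integral = d.jzs_ttest_bf(stats_, prior)
            sd = d.savage_dickey_bf(d.posterior_delta(stats_, prior), prior)
            assert sd.bf10 == pytest.approx(integral.bf10, rel=1e-3)

    def test_identical_densities_give_bf_one(self):
        prior = d.EffectSizePrior()
        flat = d.PosteriorSummary(0.0, (-2.0, 2.0), prior.pdf(0.0))
        assert d.savage_dickey_bf(flat, prior).bf10 == pytest.approx(1.0)


class TestFromTable:
    def test_matches_hand_computed_t(self):
        table = d.generate(d.SimSpec(design="two_group", n=50, seed=11))
        report = d.jzs_ttest_from_table(table, "y", "group")
        y = table.column("y").to_numpy(dtype=float)
        g = table.column("group")
        y1, y2 = y[(g == "g1").to_numpy()], y[(g == "g2").to_numpy()]
        sp = math.sqrt(((len(y1) - 1) * np.var(y1, ddof=1)
                        + (len(y2) - 1) * np.var(y2, ddof=1))
                       / (len(y1) + len(y2) - 2))
        t_hand = (y1.mean() - y2.mean()) / (sp * math.sqrt(1 / len(y1) + 1 / len(y2)))
        assert report.stats.t == pytest.approx(t_hand, rel=1e-12)
        direct = d.jzs_ttest_bf(TTestSufficientStats(t_hand, len(y1), len(y2)))
        assert report.bf.log_bf10 == pytest.approx(direct.log_bf10, abs=1e-10)

    def test_near_identical_groups_sided_symmetry(self, rng):
        y = np.concatenate([np.ones(10), np.ones(10)]) + rng.normal(0, 1e-9, 20)
        y[:10] = y[10:]  # t exactly 0 by construction
        table = d.DataTable({"y": y, "g": ["a"] * 10 + ["b"] * 10},
                            {"y": "continuous", "g": "nominal"})
        r_pos = d.jzs_ttest_from_table(table, "y", "g", hypothesis="group1_greater")
        r_neg = d.jzs_ttest_from_table(table, "y", "g", hypothesis="group2_greater")
        assert r_pos.bf.log_bf10 == pytest.approx(r_neg.bf.log_bf10, abs=1e-6)

    def test_error_cases(self):
        three = d.DataTable({"y": [1.0, 2.0, 3.0, 1.5, 2.5, 3.5],
                             "g": ["a", "b", "c"] * 2},
                            {"y": "continuous", "g": "nominal"})
        with pytest.raises(d.DataError, match="2 groups"):
            d.jzs_ttest_from_table(three, "y", "g")
        constant = d.DataTable({"y": [1.0, 1.0, 1.0, 1.0],
                                "g": ["a", "a", "b", "b"]},
                               {"y": "continuous", "g": "nominal"})
        with pytest.raises(d.DataError, match="pooled variance"):
            d.jzs_ttest_from_table(constant, "y", "g")

    def test_group_one_is_first_seen(self):
        table = d.DataTable({"y": [3.0, 1.0, 4.0, 2.0],
                             "g": ["clock", "counter", "clock", "counter"]},
                            {"y": "continuous", "g": "nominal"})
        report = d.jzs_ttest_from_table(table, "y", "g")
        assert report.descriptives[0].group == "clock"
        assert report.stats.t > 0  # clock mean is larger
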