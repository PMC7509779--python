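"""Bayes factors, Pearson correlation, hierarchical regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from flowparse.stats import (bf_ttest, bf_correlation, pearson,
                             hierarchical_regression)


def trapezoid_bf_ttest(t, n, scale=0.707, nodes=400001, span=15.0):
    """Independent brute-force quadrature for the JZS t-test Bayes factor."""
    df = n - 1
    delta = np.linspace(-span, span, nodes)
    integrand = (sps.nct.pdf(t, df, delta * np.sqrt(n))
                 * sps.cauchy.pdf(delta, 0.0, scale))
    num = np.trapezoid(integrand, delta)
    # the Cauchy tails beyond the span carry negligible likelihood mass
    return num / sps.t.pdf(t, df)


def trapezoid_bf_correlation(r, n, width=1.0, nodes=400001):
    """Independent brute-force quadrature for the correlation Bayes factor."""
    a = 1.0 / width
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, nodes)
    prior = ((1 - rho ** 2) ** (a - 1)
             / (2 ** (2 * a - 1) * special.beta(a, a)))
    lik = ((1 - rho ** 2) ** ((n - 1) / 2)
           * (1 - rho * r) ** (-(n - 1.5))
           * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2))
    lik0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return np.trapezoid(lik * prior, rho) / lik0


class TestBayesTTest:
    def test_null_favored_at_t_zero(self):
        assert bf_ttest(0.0, 30).bf10 < 1

    def test_null_evidence_grows_with_n(self):
        bfs = [bf_ttest(0.0, n).bf10 for n in (5, 10, 30, 100)]
        assert np.all(np.diff(bfs) < 0)

    def test_monotone_in_t_magnitude(self):
        bfs = [bf_ttest(t, 25).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("t,n", [(0.31, 30), (2.0, 12), (3.0, 30),
                                     (-2.5, 20), (6.06, 30)])
    def test_matches_brute_force_quadrature(self, t, n):
        ours = bf_ttest(t, n).bf10
        oracle = trapezoid_bf_ttest(t, n)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_two_sample_uses_effective_n(self):
        res = bf_ttest(2.5, 15, 15)
        df = 28
        delta = np.linspace(-15, 15, 400001)
        neff = 15 * 15 / 30
        num = np.trapezoid(sps.nct.pdf(2.5, df, delta * np.sqrt(neff))
                           * sps.cauchy.pdf(delta, 0, 0.707), delta)
        assert res.bf10 == pytest.approx(num / sps.t.pdf(2.5, df), rel=1e-6)
        assert res.n == 30

    def test_published_jasp_anchor_values(self):
        """Default-prior values printed by the standard software for
        n = 30: t = 0.31 -> ~0.20 and t = 2.17 -> ~1.47."""
        assert bf_ttest(0.31, 30).bf10 == pytest.approx(0.20, abs=0.02)
        assert bf_ttest(2.17, 30).bf10 == pytest.approx(1.47, rel=0.05)
        assert bf_ttest(6.06, 30).bf10 > 100

    def test_cross_check_against_pingouin(self):
        import pingouin as pg
        for t, n in [(1.2, 18), (2.8, 40), (-0.7, 25)]:
            assert bf_ttest(t, n).bf10 == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-6)


class TestBayesCorrelation:
    def test_null_favored_at_r_zero(self):
        assert bf_correlation(0.0, 30).bf10 < 1

    def test_monotone_in_r_and_n(self):
        bfs_r = [bf_correlation(r, 30).bf10 for r in (0.0, 0.2, 0.4, 0.6)]
        assert np.all(np.diff(bfs_r) > 0)
        bfs_n = [bf_correlation(0.4, n).bf10 for n in (10, 20, 40, 80)]
        assert np.all(np.diff(bfs_n) > 0)

    @pytest.mark.parametrize("r,n", [(0.1, 10), (0.55, 30), (-0.4, 25),
                                     (0.8, 15), (0.24, 30)])
    def test_matches_brute_force_quadrature(self, r, n):
        ours = bf_correlation(r, n).bf10
        oracle = trapezoid_bf_correlation(r, n)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_published_jasp_anchor_values(self):
        """r = 0.55, n = 30 -> ~25.6; r = 0.24, n = 30 -> ~0.50."""
        assert bf_correlation(0.55, 30).bf10 == pytest.approx(25.64, rel=0.05)
        assert bf_correlation(0.24, 30).bf10 == pytest.approx(0.50, rel=0.10)

    def test_cross_check_against_pingouin(self):
        import pingouin as pg
        for r, n in [(0.3, 20), (0.55, 30), (-0.6, 15)]:
            assert bf_correlation(r, n).bf10 == pytest.approx(
                float(pg.bayesfactor_pearson(r, n)), rel=1e-6)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            bf_correlation(1.0, 30)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonalized_vectors_uncorrelated(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y = y - y.mean() - np.dot(y - y.mean(), x - x.mean()) \
            / np.dot(x - x.mean(), x - x.mean()) * (x - x.mean())
        r, _ = pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # direct sum-formula evaluation
        num = np.sum((x - 3) * (y - y.mean()))
        den = np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - y.mean()) ** 2))
        r, p = pearson(x, y)
        assert r == pytest.approx(num / den, abs=1e-12)
        t = r * np.sqrt(3 / (1 - r ** 2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 3), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHierarchicalRegression:
    def test_normal_equations_fixture(self):
        """Two predictors, n = 10: coefficients solved by hand from the
        normal equations must match to 1e-10."""
        gen = np.random.default_rng(3)
        x1 = gen.normal(size=10)
        x2 = gen.normal(size=10)
        y = 1.5 + 2.0 * x1 - 0.8 * x2 + gen.normal(size=10)
        ladder = hierarchical_regression(y, [{"x1": x1}, {"x2": x2}])
        X = np.column_stack([np.ones(10), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        coefs = ladder.steps[1].coefficients
        assert coefs.loc["x1", "B"] == pytest.approx(beta[1], abs=1e-10)
        assert coefs.loc["x2", "B"] == pytest.approx(beta[2], abs=1e-10)

    def test_perfect_predictor_saturates_r2(self):
        x = np.linspace(0, 1, 12)
        y = 3 * x - 1
        gen = np.random.default_rng(1)
        ladder = hierarchical_regression(
            y, [{"x": x}, {"z": gen.normal(size=12)}])
        assert ladder.steps[0].r2 == pytest.approx(1.0)
        assert ladder.steps[1].delta_r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_monotone_and_beta_identity(self, rng):
        y = rng.normal(size=40)
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        ladder = hierarchical_regression(y, [{"x1": x1}, {"x2": x2}])
        r2s = [s.r2 for s in ladder.steps]
        assert r2s[1] >= r2s[0] >= 0
        # standardized beta = B * sd(x) / sd(y) in the single-predictor step
        s0 = ladder.steps[0].coefficients
        assert s0.loc["x1", "beta"] == pytest.approx(
            s0.loc["x1", "B"] * np.std(x1, ddof=1) / np.std(y, ddof=1))

    def test_step_order_leaves_full_model_unchanged(self, rng):
        y = rng.normal(size=30)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        a = hierarchical_regression(y, [{"x1": x1}, {"x2": x2}])
        b = hierarchical_regression(y, [{"x2": x2}, {"x1": x1}])
        assert a.steps[1].r2 == pytest.approx(b.steps[1].r2, abs=1e-12)

    def test_f_change_matches_scipy_reference(self, rng):
        y = rng.normal(size=25)
        x1 = rng.normal(size=25)
        x2 = rng.normal(size=25)
        ladder = hierarchical_regression(y, [{"x1": x1}, {"x2": x2}])
        s2 = ladder.steps[1]
        f = (s2.delta_r2 / 1) / ((1 - s2.r2) / (25 - 2 - 1))
        assert s2.f_change == pytest.approx(f)
        assert s2.p_change == pytest.approx(sps.f.sf(f, 1, 22))

    def test_rank_deficiency_rejected(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            hierarchical_regression(x, [{"x1": x, "x2": 2 * x}])
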