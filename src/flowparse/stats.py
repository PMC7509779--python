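"""Inferential layer: default-prior Bayes factors and hierarchical OLS.

Bayes factors follow the JASP/BayesFactor defaults.  For t-tests the
effect-size prior is Cauchy(0, 0.707) and

    BF10 = Int T_df(t; delta*sqrt(n_eff)) Cauchy(delta) d delta
           / T_df(t; 0)

with n_eff = n for one-sample/paired designs and n1*n2/(n1+n2) for
two-sample designs.  For Pearson correlations the prior on rho is a
symmetric beta(1/w, 1/w) stretched to (-1, 1) (w = 1 gives a uniform
prior), integrated against the exact sampling density of r under a
bivariate normal.  Both are evaluated by adaptive quadrature; closed-form
shortcuts are deliberately avoided so the routines can be pinned against
an independent brute-force integrator.

The two-step hierarchical regression mirrors the usual ageing-covariate
table: cumulative OLS models, R-squared change F-tests, and standardized
betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps
import statsmodels.api as sm

__all__ = [
    "BayesTestResult",
    "RegressionStep",
    "RegressionLadder",
    "bf_ttest",
    "bf_correlation",
    "pearson",
    "hierarchical_regression",
]


@dataclass(frozen=True)
class BayesTestResult:
    bf10: float
    statistic: float   # t or r
    p: float           # two-sided classical p
    n: int
    prior_scale: float

    def to_dict(self) -> dict:
        return asdict(self)


def bf_ttest(t: float, n1: int, n2: int | None = None,
             scale: float = 0.707) -> BayesTestResult:
    """JZS Bayes factor for a one-sample/paired (n2 omitted) or
    two-sample t statistic, with a Cauchy(0, scale) effect-size prior."""
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n2 is None:
        if n1 < 2:
            raise ValueError("need n >= 2")
        df = n1 - 1
        n_eff = float(n1)
        n_total = n1
    else:
        if min(n1, n2) < 2:
            raise ValueError("need at least 2 per group")
        df = n1 + n2 - 2
        n_eff = n1 * n2 / (n1 + n2)
        n_total = n1 + n2

    root_n = np.sqrt(n_eff)

    def integrand(delta):
        return (sps.nct.pdf(t, df, delta * root_n)
                * sps.cauchy.pdf(delta, loc=0.0, scale=scale))

    num, err = integrate.quad(integrand, -np.inf, np.inf,
                              epsabs=0.0, epsrel=1e-10, limit=400)
    if num <= 0 or not np.isfinite(num) or err > 1e-6 * num:
        raise RuntimeError("marginal-likelihood quadrature did not converge")
    den = sps.t.pdf(t, df)
    p = 2.0 * sps.t.sf(abs(t), df)
    return BayesTestResult(bf10=float(num / den), statistic=float(t),
                           p=float(p), n=n_total, prior_scale=scale)


def _corr_likelihood_kernel(rho, r, n):
    """Sampling density of the sample correlation r given rho, up to a
    rho-independent constant (which cancels in the Bayes factor)."""
    return ((1.0 - rho ** 2) ** ((n - 1) / 2.0)
            * (1.0 - rho * r) ** (-(n - 1.5))
            * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))


def bf_correlation(r: float, n: int, width: float = 1.0) -> BayesTestResult:
    """Bayes factor for a Pearson correlation with a stretched
    beta(1/width, 1/width) prior on rho over (-1, 1)."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("need n >= 3")
    a = 1.0 / width
    log_norm = (2 * a - 1) * np.log(2.0) + special.betaln(a, a)

    def integrand(rho):
        prior = np.exp((a - 1) * (np.log1p(rho) + np.log1p(-rho)) - log_norm)
        return _corr_likelihood_kernel(rho, r, n) * prior

    num, err = integrate.quad(integrand, -1.0, 1.0,
                              epsabs=0.0, epsrel=1e-10, limit=400)
    den = _corr_likelihood_kernel(0.0, r, n)
    if num <= 0 or not np.isfinite(num) or err > 1e-6 * num:
        raise RuntimeError("marginal-likelihood quadrature did not converge")
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return BayesTestResult(bf10=float(num / den), statistic=float(r),
                           p=float(p), n=n, prior_scale=width)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-distribution p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RegressionStep:
    step: int
    r2: float
    delta_r2: float
    f_change: float
    df_change: tuple
    p_change: float
    coefficients: pd.DataFrame = field(repr=False)  # B, SE_B, beta, p per predictor


@dataclass(frozen=True)
class RegressionLadder:
    steps: list

    def to_frame(self) -> pd.DataFrame:
        """Long-format table mirroring the usual published layout."""
        rows = []
        for s in self.steps:
            rows.append({"step": s.step, "predictor": "",
                         "R2": s.r2, "delta_R2": s.delta_r2,
                         "F_change": s.f_change,
                         "df1": s.df_change[0], "df2": s.df_change[1],
                         "p_change": s.p_change,
                         "B": np.nan, "SE_B": np.nan, "beta": np.nan})
            for name, c in s.coefficients.iterrows():
                rows.append({"step": s.step, "predictor": name,
                             "R2": np.nan, "delta_R2": np.nan,
                             "F_change": np.nan, "df1": np.nan, "df2": np.nan,
                             "p_change": np.nan,
                             "B": c["B"], "SE_B": c["SE_B"], "beta": c["beta"]})
        return pd.DataFrame(rows)


def hierarchical_regression(y, step_predictors: list) -> RegressionLadder:
    """Cumulative-step OLS ladder with R-squared-change F tests.

    ``step_predictors`` is an ordered list; each element is a DataFrame (or
    dict of name -> vector) of the predictors *added* at that step.  Betas
    are standardized slopes B * sd(x) / sd(y).
    """
    y = np.asarray(y, dtype=float)
    blocks = []
    for block in step_predictors:
        df = pd.DataFrame(block)
        if len(df) != len(y):
            raise ValueError("predictor length mismatch")
        blocks.append(df)
    total_k = sum(b.shape[1] for b in blocks)
    if len(y) <= total_k + 1:
        raise ValueError("too few observations for the requested ladder")

    sd_y = np.std(y, ddof=1)
    steps = []
    prev_r2 = 0.0
    cumulative = pd.DataFrame(index=blocks[0].index)
    for i, block in enumerate(blocks, start=1):
        cumulative = pd.concat([cumulative, block], axis=1)
        X = sm.add_constant(cumulative)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("rank-deficient design at step %d" % i)
        fit = sm.OLS(y, X).fit()
        r2 = float(fit.rsquared)
        k_added = block.shape[1]
        k_total = cumulative.shape[1]
        df2 = len(y) - k_total - 1
        delta = r2 - prev_r2
        f_change = (delta / k_added) / ((1.0 - r2) / df2) if r2 < 1 else np.inf
        p_change = float(sps.f.sf(f_change, k_added, df2))
        coefs = pd.DataFrame({
            "B": fit.params.drop("const"),
            "SE_B": fit.bse.drop("const"),
            "p": fit.pvalues.drop("const"),
        })
        coefs["beta"] = [
            fit.params[name] * np.std(cumulative[name], ddof=1) / sd_y
            for name in coefs.index
        ]
        steps.append(RegressionStep(step=i, r2=r2, delta_r2=float(delta),
                                    f_change=float(f_change),
                                    df_change=(k_added, df2),
                                    p_change=p_change,
                                    coefficients=coefs[["B", "SE_B", "beta", "p"]]))
        prev_r2 = r2
    return RegressionLadder(steps=steps)
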