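"""Statistical kernel: t-tests with effect size r, one-way ANOVA with
omega-squared, simple linear regression, and quasi-binomial logistic fits.

Every t-style result carries the correlation-scale effect size
r = sqrt(t^2 / (t^2 + df)), the convention used throughout the membrane/
water-soluble comparisons; r is computed from t and df, not from the raw
data, so printed (t, df) pairs reproduce their printed r exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "StatsError",
    "TTestResult",
    "AnovaResult",
    "LinRegResult",
    "GlmFit",
    "effect_size_r",
    "paired_t",
    "welch_t",
    "one_way_anova",
    "linear_regression",
    "quasibinomial_irls",
    "benjamini_hochberg",
]


class StatsError(ValueError):
    """Raised when a statistic is undefined for the given input."""


def effect_size_r(t: float, df: float) -> float:
    """Correlation-scale effect size r = sqrt(t^2/(t^2 + df)).

    Defined for df > 0; always in [0, 1].
    """
    if df <= 0:
        raise StatsError(f"df must be positive, got {df}")
    t2 = float(t) * float(t)
    return math.sqrt(t2 / (t2 + float(df)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    r: float
    kind: str  # "paired" or "welch"


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    omega_sq: float


@dataclass(frozen=True)
class LinRegResult:
    slope: float
    intercept: float
    r: float
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class GlmFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    dispersion: float
    converged: bool
    n_iter: int

    @property
    def z_slope(self) -> float:
        return self.slope / self.se_slope


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(x, y) -> TTestResult:
    """Paired t-test on the differences x - y; df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired_t requires two equal-length 1-d vectors")
    n = x.size
    if n < 2:
        raise StatsError("paired_t requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical vectors: t is exactly 0 by convention
            return TTestResult(0.0, float(n - 1), 1.0, 0.0, "paired")
        raise StatsError("zero-variance nonzero differences: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = float(n - 1)
    return TTestResult(float(t), df, _two_tailed_p(t, df), effect_size_r(t, df), "paired")


def welch_t(x, y) -> TTestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise StatsError("welch_t requires n >= 2 in each group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, float(nx + ny - 2), 1.0, 0.0, "welch")
        raise StatsError("zero variance in both groups: t undefined")
    sx, sy = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (
        (sx**2 / (nx - 1) if nx > 1 else 0.0) + (sy**2 / (ny - 1) if ny > 1 else 0.0)
    )
    return TTestResult(float(t), float(df), _two_tailed_p(t, df), effect_size_r(t, df), "welch")


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA with omega-squared effect size.

    omega^2 = (SS_between - df_between * MS_within) / (SS_total + MS_within),
    clamped at 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("one_way_anova requires >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise StatsError("each group needs n >= 2")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = allv.size - len(arrays)
    if ss_within == 0:
        raise StatsError("zero within-group variance: F undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    ss_total = ss_between + ss_within
    omega = (ss_between - df_between * ms_within) / (ss_total + ms_within)
    return AnovaResult(float(F), df_between, df_within, p, max(0.0, float(omega)))


def linear_regression(x, y) -> LinRegResult:
    """Ordinary least squares y ~ x with the slope F-test and |r|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise StatsError("linear_regression requires n >= 3")
    if x.var() == 0:
        raise StatsError("zero variance in x")
    res = sps.linregress(x, y)
    r = abs(float(res.rvalue)) if np.isfinite(res.rvalue) else 0.0
    df_den = n - 2
    if r >= 1.0:
        F = math.inf
        p = 0.0
    else:
        F = r * r * df_den / (1.0 - r * r)
        p = float(sps.f.sf(F, 1, df_den))
    return LinRegResult(
        float(res.slope), float(res.intercept), r, float(F), 1, df_den, p
    )


def quasibinomial_irls(y01, x, tol: float = 1e-8, maxiter: int = 100) -> GlmFit:
    """Quasi-binomial logistic regression of a 0/1 response on one predictor.

    Fit by iteratively reweighted least squares (logit link); the dispersion
    parameter is the Pearson chi-square divided by the residual degrees of
    freedom (n - 2), and standard errors are scaled by sqrt(dispersion).
    Perfect separation is reported as non-convergence with NaN coefficients.
    """
    y = np.asarray(y01, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise StatsError("y and x must have equal length")
    if y.size < 10:
        raise StatsError("quasibinomial fit requires n >= 10")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise StatsError("response must be 0/1")
    X = sm.add_constant(x)
    failed = GlmFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, 0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(method="IRLS", maxiter=maxiter, tol=tol, scale="X2")
    except (PerfectSeparationError, PerfectSeparationWarning, RuntimeWarning, ValueError):
        return failed
    n_iter = len(res.fit_history.get("deviance", [])) if hasattr(res, "fit_history") else 0
    converged = bool(getattr(res, "converged", True))
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        return failed
    # huge coefficients signal quasi-separation even when IRLS "converges"
    if np.abs(params).max() > 1e3:
        return failed
    return GlmFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        dispersion=float(res.scale),
        converged=converged,
        n_iter=max(0, n_iter - 1),
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiple-testing aid)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
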