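"""Regression models for the pressure-feature relationships.

Two fits carry the run-level physiology: a piecewise f_o vs transmural
pressure fit with independent ordinary-least-squares lines in the low
(S1, p_t below the breakpoint, default 0.75 kPa) and high (S2, up to
2 kPa) pressure regimes, and a plain linear SL vs bronchial-pressure fit.
Which pressure drives a feature is decided by a delta-BIC comparison of
single-predictor Gaussian linear models against the intercept-only null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

log = logging.getLogger(__name__)

#: tie-break precedence when candidate ΔBIC values coincide within 1e-9
PREDICTOR_PRECEDENCE = ("p_t", "p_b", "p_icas", "null")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    rss: float
    n: int


@dataclass
class PiecewiseSlopeFit:
    """Independent S1/S2 regression lines of a feature against p_t (kPa).

    The regions are half-open: S1 = [0, breakpoint), S2 = [breakpoint,
    upper_limit]; the boundary point belongs to S2.  No continuity is
    imposed — the two lines are fitted separately.
    """

    s1_slope: float
    s2_slope: float
    s1_intercept: float
    s2_intercept: float
    breakpoint: float
    upper_limit: float
    n1: int
    n2: int
    r2_1: float
    r2_2: float


@dataclass
class BICComparison:
    """ΔBIC of single-predictor models relative to the intercept-only null."""

    bic: dict = field(default_factory=dict)
    delta_bic: dict = field(default_factory=dict)
    best: str = "null"


def fit_linear(x, y) -> LinearFit:
    """OLS line y = slope*x + intercept with r^2 and residual sum of squares."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: singular design")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     r2=float(res.rsquared), rss=float(res.ssr), n=int(x.size))


def fit_piecewise(x, y, breakpoint=0.75, upper_limit=2.0) -> PiecewiseSlopeFit:
    """Fit the S1/S2 lines on data restricted to [0, upper_limit].

    Raises (naming the region) when a region holds fewer than 3 points.
    NaNs in either variable are dropped first.
    """
    if not 0 < breakpoint < upper_limit:
        raise ValueError("need 0 < breakpoint < upper_limit")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = ~(np.isnan(x) | np.isnan(y)) & (x >= 0) & (x <= upper_limit)
    x, y = x[keep], y[keep]
    in_s1 = x < breakpoint
    fits = {}
    for name, sel in (("S1", in_s1), ("S2", ~in_s1)):
        if sel.sum() < 3:
            raise ValueError(
                f"region {name} holds only {int(sel.sum())} points "
                f"(need >= 3) within [0, {upper_limit}] kPa")
        fits[name] = fit_linear(x[sel], y[sel])
    return PiecewiseSlopeFit(
        s1_slope=fits["S1"].slope, s2_slope=fits["S2"].slope,
        s1_intercept=fits["S1"].intercept, s2_intercept=fits["S2"].intercept,
        breakpoint=breakpoint, upper_limit=upper_limit,
        n1=fits["S1"].n, n2=fits["S2"].n,
        r2_1=fits["S1"].r2, r2_2=fits["S2"].r2)


def _bic(rss: float, n: int, k_mean: int) -> float:
    """Gaussian BIC up to model-independent constants.

    n*ln(RSS/n) + k*ln(n) with k = mean parameters + 1 for the profiled
    variance; the additive n*ln(2*pi) + n term is identical across models
    and cancels in any ΔBIC, so it is omitted.
    """
    rss = max(rss, np.finfo(float).tiny)
    return n * np.log(rss / n) + (k_mean + 1) * np.log(n)


def delta_bic(y, candidate_predictors: dict) -> BICComparison:
    """ΔBIC model selection among single-pressure predictors of ``y``.

    Each candidate model is y ~ 1 + pressure; the null is y ~ 1.  ΔBIC =
    BIC(model) - BIC(null), so ΔBIC(null) = 0 by definition and the most
    negative ΔBIC wins.  Constant (degenerate) predictors are skipped with
    a warning; ties within 1e-9 fall back to the fixed precedence
    p_t > p_b > p_icas > null.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations for ΔBIC selection")
    rss_null = float(np.sum((y - y.mean()) ** 2))
    bic_null = _bic(rss_null, n, 1)
    comp = BICComparison(bic={"null": bic_null}, delta_bic={"null": 0.0})
    for name, x in candidate_predictors.items():
        x = np.asarray(x, dtype=np.float64)
        if x.size != n:
            raise ValueError(f"predictor {name!r} length {x.size} != {n}")
        if np.ptp(x) == 0:
            log.warning("predictor %r is constant; skipped", name)
            continue
        fit = fit_linear(x, y)
        b = _bic(fit.rss, n, 2)
        comp.bic[name] = b
        comp.delta_bic[name] = b - bic_null

    def rank(name):
        prec = (PREDICTOR_PRECEDENCE.index(name)
                if name in PREDICTOR_PRECEDENCE else len(PREDICTOR_PRECEDENCE))
        return (round(comp.delta_bic[name] / 1e-9), prec)

    comp.best = min(comp.delta_bic, key=rank)
    return comp
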