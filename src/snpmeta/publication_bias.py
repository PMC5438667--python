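"""Small-study / publication-bias diagnostics.

Two classical funnel-asymmetry tests:

* Egger regression — ordinary least squares of the standardised effect
  y_i/se_i on the precision 1/se_i; under no small-study effect the
  intercept is 0, tested with a t statistic on k-2 df.
* Begg-Mazumdar rank correlation — Kendall's tau between the
  variance-stabilised deviates u_i = (y_i - mu_fixed)/sqrt(v_i - 1/sum w)
  and the variances v_i, with the continuity-corrected normal
  approximation z = (|S| - 1)/sqrt(Var S).

Both need at least three studies.  A funnel-plot data series (log OR vs
SE with pseudo-95% guide lines) is exposed for plotting; no graphic is
rendered here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientStudiesError
from .genetic_models import Z95, EffectEstimate

__all__ = ["EggerResult", "BeggResult", "egger_test", "begg_test", "funnel_series"]


@dataclass(frozen=True)
class EggerResult:
    """Egger regression intercept (standardised-effect units) and its
    two-sided t test on k-2 df; the slope estimates the bias-adjusted
    pooled log OR."""

    intercept: float
    intercept_se: float
    slope: float
    t_stat: float
    p_value: float
    k: int


@dataclass(frozen=True)
class BeggResult:
    """Kendall statistics for the Begg-Mazumdar test: raw S
    (concordant minus discordant pairs), tie-corrected tau, and the
    continuity-corrected normal z with its two-sided p."""

    kendall_s: int
    tau: float
    z: float
    p_value: float
    k: int


def egger_test(effects: list[EffectEstimate]) -> EggerResult:
    """Egger's linear-regression test for funnel-plot asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Egger's test needs at least 3 studies")
    y = np.array([e.log_or / e.se for e in effects])
    x = np.array([1.0 / e.se for e in effects])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return EggerResult(
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        slope=float(fit.params[1]),
        t_stat=float(fit.tvalues[0]),
        p_value=float(fit.pvalues[0]),
        k=k,
    )


def _kendall_var_s(u: np.ndarray, v: np.ndarray) -> float:
    """Variance of Kendall's S with the standard tie correction."""
    n = len(u)

    def tie_sizes(x: np.ndarray) -> np.ndarray:
        _, counts = np.unique(x, return_counts=True)
        return counts[counts > 1].astype(float)

    t = tie_sizes(u)
    s = tie_sizes(v)
    var = (n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5)) - np.sum(s * (s - 1) * (2 * s + 5))) / 18.0
    if n > 2:
        var += (np.sum(t * (t - 1) * (t - 2)) * np.sum(s * (s - 1) * (s - 2))) / (9.0 * n * (n - 1) * (n - 2))
    var += (np.sum(t * (t - 1)) * np.sum(s * (s - 1))) / (2.0 * n * (n - 1))
    return float(var)


def begg_test(effects: list[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for funnel-plot asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Begg's test needs at least 3 studies")
    y = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    # variance-stabilised deviates: subtracting the pooled mean removes
    # 1/sum(w) from each study's variance
    vstar = v - 1.0 / float(np.sum(w))
    u = (y - mu) / np.sqrt(vstar)

    s_count = 0
    for i in range(k):
        for j in range(i + 1, k):
            s_count += int(np.sign(u[j] - u[i]) * np.sign(v[j] - v[i]))

    def n_pairs_untied(x: np.ndarray) -> float:
        n0 = k * (k - 1) / 2.0
        _, counts = np.unique(x, return_counts=True)
        return n0 - float(np.sum(counts * (counts - 1) / 2.0))

    denom = math.sqrt(n_pairs_untied(u) * n_pairs_untied(v))
    tau = s_count / denom if denom > 0 else 0.0
    var_s = _kendall_var_s(u, v)
    z = 0.0 if s_count == 0 else (abs(s_count) - 1) / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(z))
    return BeggResult(kendall_s=s_count, tau=float(tau), z=float(z), p_value=min(p, 1.0), k=k)


def funnel_series(
    effects: list[tuple[str, EffectEstimate]], pooled_log_or: float | None = None
) -> pd.DataFrame:
    """Per-study funnel coordinates (study_id, log_or, se) plus pseudo-95%
    guide-line bounds around ``pooled_log_or`` (fixed-effect mean when not
    given)."""
    ids = [sid for sid, _ in effects]
    y = np.array([e.log_or for _, e in effects])
    se = np.array([e.se for _, e in effects])
    if pooled_log_or is None:
        w = 1.0 / se**2
        pooled_log_or = float(np.sum(w * y) / np.sum(w))
    return pd.DataFrame(
        {
            "study_id": ids,
            "log_or": y,
            "se": se,
            "guide_low": pooled_log_or - Z95 * se,
            "guide_high": pooled_log_or + Z95 * se,
        }
    )
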