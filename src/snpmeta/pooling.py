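"""Inverse-variance pooling with DerSimonian-Laird random effects.

Study log odds ratios y_i with variances v_i are combined either under a
common-effect (fixed) model with weights w_i = 1/v_i, or under an additive
between-study variance tau^2 estimated by the DerSimonian-Laird moment
formula

    tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)),   S_r = sum w_i^r,

where Q = sum w_i (y_i - mu_hat)^2 is Cochran's heterogeneity statistic
(chi-square, k-1 df under homogeneity) and I^2 = max(0, (Q-(k-1))/Q) * 100
is the percentage of total variability attributable to heterogeneity.

Model choice follows the conventional screening rule: random effects when
the Q test gives p < 0.1 or I^2 > 50%, fixed effects otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import InsufficientStudiesError
from .genetic_models import Z95, EffectEstimate, GeneticModel, study_effects
from .study_io import StudySet

__all__ = [
    "PoolingModel",
    "PooledResult",
    "cochran_q",
    "pool_fixed",
    "pool_random_dl",
    "select_model",
    "analyze",
    "single_study_result",
]


class PoolingModel(Enum):
    FIXED = "Fixed"
    RANDOM = "Random"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its inference and heterogeneity summary.

    ``weights`` are the relative (normalised) study weights under the model
    actually used; ``tau2`` is on the squared-log-OR scale.  ``p_q`` is NaN
    when k = 1 (heterogeneity is undefined for a single study).
    """

    model_used: PoolingModel
    pooled_log_or: float
    se_log: float
    z: float
    p_value: float
    q: float
    p_q: float
    i2: float
    tau2: float
    weights: tuple[float, ...]
    k: int

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.pooled_log_or - Z95 * self.se_log)

    @property
    def ci_high(self) -> float:
        return math.exp(self.pooled_log_or + Z95 * self.se_log)


def _arrays(effects: list[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.log_or for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return y, v


def _het(y: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    k = len(y)
    p_q = float(stats.chi2.sf(q, df=k - 1))
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, p_q, i2


def cochran_q(effects: list[EffectEstimate]) -> tuple[float, float, float]:
    """Cochran's Q, its chi-square p-value (k-1 df) and I^2 (percent)."""
    if len(effects) < 2:
        raise InsufficientStudiesError("heterogeneity needs at least 2 studies")
    y, v = _arrays(effects)
    return _het(y, v)


def _finish(
    model: PoolingModel,
    y: np.ndarray,
    w: np.ndarray,
    q: float,
    p_q: float,
    i2: float,
    tau2: float,
) -> PooledResult:
    sw = float(np.sum(w))
    mu = float(np.sum(w * y) / sw)
    se = 1.0 / math.sqrt(sw)
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PooledResult(
        model_used=model,
        pooled_log_or=mu,
        se_log=se,
        z=z,
        p_value=p,
        q=q,
        p_q=p_q,
        i2=i2,
        tau2=tau2,
        weights=tuple(np.asarray(w / sw, dtype=float)),
        k=len(y),
    )


def pool_fixed(effects: list[EffectEstimate]) -> PooledResult:
    """Inverse-variance common-effect pool (weights 1/v_i)."""
    if len(effects) == 0:
        raise InsufficientStudiesError("cannot pool an empty effect list")
    y, v = _arrays(effects)
    if len(y) == 1:
        q, p_q, i2 = 0.0, float("nan"), 0.0
    else:
        q, p_q, i2 = _het(y, v)
    return _finish(PoolingModel.FIXED, y, 1.0 / v, q, p_q, i2, tau2=0.0)


def pool_random_dl(effects: list[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pool."""
    if len(effects) < 2:
        raise InsufficientStudiesError("random-effects pooling needs at least 2 studies")
    y, v = _arrays(effects)
    q, p_q, i2 = _het(y, v)
    w = 1.0 / v
    s1 = float(np.sum(w))
    s2 = float(np.sum(w * w))
    tau2 = max(0.0, (q - (len(y) - 1)) / (s1 - s2 / s1))
    return _finish(PoolingModel.RANDOM, y, 1.0 / (v + tau2), q, p_q, i2, tau2=tau2)


def select_model(p_q: float, i2: float, het_p: float = 0.1, i2_threshold: float = 50.0) -> PoolingModel:
    """Heterogeneity screening rule: RANDOM iff p_Q < het_p or I^2 > i2_threshold."""
    if p_q < het_p or i2 > i2_threshold:
        return PoolingModel.RANDOM
    return PoolingModel.FIXED


def single_study_result(effect: EffectEstimate) -> PooledResult:
    """Wrap a lone study's crude estimate as a degenerate pooled result
    (used by single-study strata, where pooling is an identity)."""
    return PooledResult(
        model_used=PoolingModel.FIXED,
        pooled_log_or=effect.log_or,
        se_log=effect.se,
        z=effect.log_or / effect.se,
        p_value=float(2.0 * stats.norm.sf(abs(effect.log_or / effect.se))),
        q=0.0,
        p_q=float("nan"),
        i2=0.0,
        tau2=0.0,
        weights=(1.0,),
        k=1,
    )


def analyze(
    studies: StudySet,
    model: GeneticModel,
    het_p: float = 0.1,
    i2_threshold: float = 50.0,
) -> PooledResult:
    """Full pooled analysis of a study set under one genetic model.

    Computes per-study crude log ORs, screens heterogeneity with Cochran's
    Q and I^2, and pools under the model the screening rule selects.
    """
    if len(studies) < 2:
        raise InsufficientStudiesError("analysis needs at least 2 studies")
    effects = [e for _, e in study_effects(studies, model)]
    _, p_q, i2 = cochran_q(effects)
    if select_model(p_q, i2, het_p, i2_threshold) is PoolingModel.RANDOM:
        return pool_random_dl(effects)
    return pool_fixed(effects)
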