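"""Random-effects meta-regression on study-level moderators.

Explains between-study variation in log odds ratios with categorical
moderators (here: ethnicity, source of controls).  Moderators are
dummy-coded against a reference level (the first level observed in input
order).  Residual between-study variance tau^2_res is estimated by the
method of moments — the DerSimonian-Laird generalisation to a design
matrix X:

    P       = W - W X (X' W X)^{-1} X' W,   W = diag(1/v_i)
    Q_res   = y' P y
    tau^2   = max(0, (Q_res - (k - p)) / tr(P))

followed by weighted least squares with weights 1/(v_i + tau^2_res),
z-based coefficient tests and an omnibus Wald chi-square test that all
moderator coefficients are simultaneously zero.  With no moderators the
fit collapses to the DerSimonian-Laird pooled mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientStudiesError
from .genetic_models import EffectEstimate

__all__ = ["Coefficient", "MetaRegResult", "meta_regress"]


@dataclass(frozen=True)
class Coefficient:
    name: str
    estimate: float
    se: float
    z: float
    p_value: float


@dataclass(frozen=True)
class MetaRegResult:
    coefficients: tuple[Coefficient, ...]
    residual_tau2: float
    omnibus_chi2: float
    omnibus_p: float
    k: int
    n_params: int
    reference_levels: tuple[tuple[str, str], ...]

    @property
    def fitted(self) -> tuple[float, ...]:
        return self._fitted  # type: ignore[attr-defined]


def _design(
    moderators: Mapping[str, Sequence[str]], factors: Sequence[str], k: int
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    cols: list[np.ndarray] = [np.ones(k)]
    names: list[str] = ["intercept"]
    refs: list[tuple[str, str]] = []
    for factor in factors:
        if factor not in moderators:
            raise DegenerateDesignError(f"no moderator values supplied for factor {factor!r}")
        labels = list(moderators[factor])
        if len(labels) != k:
            raise DegenerateDesignError(
                f"factor {factor!r} has {len(labels)} labels for {k} studies"
            )
        levels = list(dict.fromkeys(labels))  # first-occurrence order
        if len(levels) < 2:
            raise DegenerateDesignError(
                f"factor {factor!r} has a single observed level {levels[0]!r}"
            )
        ref = levels[0]
        refs.append((factor, ref))
        for level in levels[1:]:
            count = labels.count(level)
            if count == 1:
                warnings.warn(
                    f"factor {factor!r}: level {level!r} is observed in one study only",
                    stacklevel=3,
                )
            cols.append(np.array([1.0 if lab == level else 0.0 for lab in labels]))
            names.append(f"{factor}[{level}]")
    return np.column_stack(cols), names, refs


def meta_regress(
    effects: Sequence[EffectEstimate],
    moderators: Mapping[str, Sequence[str]],
    factors: Sequence[str],
) -> MetaRegResult:
    """Fit a random-effects meta-regression of log ORs on ``factors``.

    ``moderators`` maps each factor name to one categorical label per
    study, in study order.  ``factors`` may be empty, in which case the
    intercept-only fit reproduces the DerSimonian-Laird pooled estimate.
    """
    k = len(effects)
    y = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    X, names, refs = _design(moderators, factors, k)
    p = X.shape[1]
    if k <= p:
        raise InsufficientStudiesError(
            f"need more studies ({k}) than fitted parameters ({p})"
        )
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDesignError(
            f"design matrix is rank-deficient; factors {list(factors)} are collinear"
        )

    # method-of-moments residual tau^2
    W = np.diag(1.0 / v)
    XtWX_inv = np.linalg.inv(X.T @ W @ X)
    P = W - W @ X @ XtWX_inv @ X.T @ W
    q_res = float(y @ P @ y)
    tau2 = max(0.0, (q_res - (k - p)) / float(np.trace(P)))

    # WLS under the estimated residual heterogeneity, fixed scale (z tests)
    Wstar = np.diag(1.0 / (v + tau2))
    cov = np.linalg.inv(X.T @ Wstar @ X)
    beta = cov @ X.T @ Wstar @ y
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    coefs = tuple(
        Coefficient(name=n, estimate=float(b), se=float(s), z=float(zz), p_value=float(pp))
        for n, b, s, zz, pp in zip(names, beta, se, z, pvals)
    )

    if p > 1:
        b_mod = beta[1:]
        cov_mod = cov[1:, 1:]
        chi2 = float(b_mod @ np.linalg.inv(cov_mod) @ b_mod)
        omnibus_p = float(stats.chi2.sf(chi2, df=p - 1))
    else:
        chi2, omnibus_p = 0.0, float("nan")

    result = MetaRegResult(
        coefficients=coefs,
        residual_tau2=tau2,
        omnibus_chi2=chi2,
        omnibus_p=omnibus_p,
        k=k,
        n_params=p,
        reference_levels=tuple(refs),
    )
    object.__setattr__(result, "_fitted", tuple(float(x) for x in X @ beta))
    return result
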