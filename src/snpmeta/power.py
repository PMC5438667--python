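"""Post-hoc power of a pooled case-control comparison.

Treats the meta-analysis as one large 2x2 comparison of exposure
(risk-genotype carriage or allele) between cases and controls.  Given a
control exposure frequency p0 and a detectable odds ratio, the implied
case frequency is

    p1 = OR * p0 / (1 + p0 * (OR - 1))

and the two-sided normal-approximation power of the log-OR test is

    power = Phi(|log OR| / SE - z_{1-a/2}) + Phi(-|log OR| / SE - z_{1-a/2})

with SE the Woolf standard error at the expected cell counts.  At OR = 1
the formula returns exactly alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .genetic_models import GeneticModel, make_2x2
from .study_io import StudySet

__all__ = ["PowerResult", "study_power", "control_exposure_freq", "meta_power"]


@dataclass(frozen=True)
class PowerResult:
    power: float
    alpha: float
    assumed_or: float
    exposure_freq_controls: float
    n_cases: int
    n_controls: int


def study_power(
    n_cases: int,
    n_controls: int,
    p0: float,
    or_: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Power to detect odds ratio ``or_`` with ``n_cases``/``n_controls``
    and control exposure frequency ``p0`` at two-sided level ``alpha``."""
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"control exposure frequency must be in (0,1), got {p0}")
    if or_ <= 0:
        raise ValidationError(f"odds ratio must be positive, got {or_}")
    if n_cases <= 0 or n_controls <= 0:
        raise ValidationError("group sizes must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    p1 = or_ * p0 / (1.0 + p0 * (or_ - 1.0))
    se = math.sqrt(
        1.0 / (n_cases * p1)
        + 1.0 / (n_cases * (1.0 - p1))
        + 1.0 / (n_controls * p0)
        + 1.0 / (n_controls * (1.0 - p0))
    )
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    shift = abs(math.log(or_)) / se
    power = float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))
    return PowerResult(
        power=power,
        alpha=alpha,
        assumed_or=or_,
        exposure_freq_controls=p0,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def control_exposure_freq(studies: StudySet, model: GeneticModel) -> float:
    """Pooled exposed proportion among controls under ``model``
    (allele-model denominators count alleles, not people)."""
    exposed = 0
    total = 0
    for s in studies:
        t = make_2x2(s, model)
        exposed += t.c
        total += t.c + t.d
    if total == 0:
        raise ValidationError("no control observations")
    return exposed / total


def meta_power(
    studies: StudySet,
    or_: float,
    alpha: float = 0.05,
    model: GeneticModel = GeneticModel.DOMINANT,
) -> PowerResult:
    """Post-hoc power of the whole study set, using the pooled control
    exposure frequency under ``model`` (dominant carriage by default)."""
    n_cases = sum(s.cases.n for s in studies)
    n_controls = sum(s.controls.n for s in studies)
    p0 = control_exposure_freq(studies, model)
    return study_power(n_cases, n_controls, p0, or_, alpha)
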