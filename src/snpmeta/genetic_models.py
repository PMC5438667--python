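"""Genetic-model contrasts and per-study odds-ratio estimates.

A biallelic genotype distribution (CC/CT/TT) collapses to a 2x2
exposure-by-outcome table under three standard contrasts:

* allele     — T vs. C, counting alleles (2 per person);
* dominant   — carriers (CT+TT) vs. CC;
* recessive  — TT vs. CT+CC.

Each 2x2 yields a crude odds ratio with a Woolf (log-scale, delta-method)
standard error, the form required by inverse-variance pooling.  When a cell
is zero the Haldane-Anscombe continuity correction adds 0.5 to all four
cells before taking logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import UndefinedEffectError, ValidationError
from .study_io import Study, StudySet

__all__ = [
    "GeneticModel",
    "TwoByTwo",
    "EffectEstimate",
    "make_2x2",
    "estimate_effect",
    "study_effects",
    "Z95",
]

#: Fixed 95% normal quantile used for all confidence intervals.
Z95 = 1.96


class GeneticModel(Enum):
    """The three genotype-collapsing contrasts."""

    ALLELE = "T vs. C"
    DOMINANT = "CT+TT vs. CC"
    RECESSIVE = "TT vs. CT+CC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: a/b exposed/unexposed cases, c/d
    exposed/unexposed controls.  Allele-model entries are allele counts
    (two per person); the other models count people."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study log odds ratio with its Woolf standard error.

    ``or_`` and the CI bounds are on the odds-ratio scale; ``corrected``
    records whether the 0.5 continuity correction was applied.
    """

    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0 or not math.isfinite(self.se):
            raise ValidationError(f"standard error must be positive and finite, got {self.se}")

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z95 * self.se)

    @property
    def variance(self) -> float:
        return self.se * self.se


def make_2x2(study: Study, model: GeneticModel) -> TwoByTwo:
    """Collapse a study's genotype counts into a 2x2 table for ``model``."""
    cases, controls = study.cases, study.controls
    if model is GeneticModel.ALLELE:
        return TwoByTwo(cases.t_alleles, cases.c_alleles, controls.t_alleles, controls.c_alleles)
    if model is GeneticModel.DOMINANT:
        return TwoByTwo(cases.ct + cases.tt, cases.cc, controls.ct + controls.tt, controls.cc)
    if model is GeneticModel.RECESSIVE:
        return TwoByTwo(cases.tt, cases.cc + cases.ct, controls.tt, controls.cc + controls.ct)
    raise ValueError(f"unknown genetic model {model!r}")  # pragma: no cover


def estimate_effect(table: TwoByTwo, cc_increment: float = 0.5) -> EffectEstimate:
    """Crude log odds ratio and Woolf SE for a 2x2 table.

    If any cell is zero, ``cc_increment`` (default 0.5, Haldane-Anscombe)
    is added to all four cells and the estimate is flagged ``corrected``.
    A table with no exposed observations in either group (a = c = 0), or
    none unexposed (b = d = 0), carries no information about the odds
    ratio and raises :class:`UndefinedEffectError`.
    """
    a, b, c, d = table.cells
    if a + b == 0 or c + d == 0:
        raise UndefinedEffectError("a study margin (cases or controls) is empty")
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise UndefinedEffectError("odds ratio undefined: an exposure margin is entirely zero")
    corrected = 0 in table.cells
    if corrected:
        fa, fb, fc, fd = (x + cc_increment for x in table.cells)
    else:
        fa, fb, fc, fd = map(float, table.cells)
    log_or = math.log(fa * fd / (fb * fc))
    se = math.sqrt(1.0 / fa + 1.0 / fb + 1.0 / fc + 1.0 / fd)
    return EffectEstimate(log_or=log_or, se=se, corrected=corrected)


def study_effects(
    studies: StudySet, model: GeneticModel, cc_increment: float = 0.5
) -> list[tuple[str, EffectEstimate]]:
    """Per-study effect estimates under ``model``, input order preserved."""
    if len(studies) == 0:
        raise ValidationError("empty study set")
    out: list[tuple[str, EffectEstimate]] = []
    for s in studies:
        try:
            out.append((s.study_id, estimate_effect(make_2x2(s, model), cc_increment)))
        except UndefinedEffectError as exc:
            raise UndefinedEffectError(f"study {s.study_id!r}: {exc}") from exc
    return out
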