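"""Synthetic study-ensemble generator.

Generates case-control genotype-count studies with the statistical
structure the analysis pipeline assumes, so that every stage can be
exercised and calibrated without external data:

* control genotypes are multinomial draws from Hardy-Weinberg proportions
  ((1-q)^2, 2q(1-q), q^2) at a study-specific risk-allele frequency q;
* disease risk is multiplicative per allele: a study with per-allele odds
  ratio R tilts the genotype probabilities of cases by (1, R, R^2),
  renormalised — so the allele-model contrast targets R asymptotically;
* between-study heterogeneity adds Normal(0, tau^2) noise to the log
  per-allele OR of each study;
* moderator labels (ethnicity, source of controls) are assigned by fixed
  proportions, optionally with level-specific log-OR shifts;
* an optional small-study bias mechanism retains each study with
  probability increasing in its one-sided allele-model z score,
  suppressing small null studies and producing funnel asymmetry.

Randomness is a single global seed feeding one counter-based stream per
study (``default_rng([seed, index])``), so enlarging an ensemble never
shifts the draws of earlier studies, and the bias mechanism's retention
draw never perturbs genotype draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .genetic_models import estimate_effect
from .genetic_models import GeneticModel, make_2x2
from .study_io import Ethnicity, GenotypeCounts, SourceOfControls, Study, StudySet

__all__ = ["SimScenario", "simulate_studies", "simulate_biased", "fixture_like_scenario"]

SizeSpec = int | tuple[int, int] | Sequence[int]
FreqSpec = float | tuple[float, float]


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated ensemble.

    ``case_sizes``/``control_sizes`` may be a fixed size, a (low, high)
    sampling range, or an explicit per-study list.  ``maf`` is the control
    risk-allele frequency (fixed or a uniform range).  ``or_allele`` is
    the per-allele odds ratio and ``tau`` the between-study SD of its log.
    ``ethnicity_probs``/``soc_probs`` give label proportions;
    ``ethnicity_shifts`` adds a log-OR shift per ethnicity level.
    ``bias_strength`` scales the small-study suppression used by
    :func:`simulate_biased`.
    """

    n_studies: int = 13
    case_sizes: SizeSpec = (200, 5000)
    control_sizes: SizeSpec = (200, 5000)
    maf: FreqSpec = (0.30, 0.45)
    or_allele: float = 1.0
    tau: float = 0.0
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Caucasian": 0.7, "Asian": 0.15, "African-American": 0.1, "Mixed": 0.05}
    )
    soc_probs: Mapping[str, float] = field(default_factory=lambda: {"HB": 0.4, "PB": 0.6})
    ethnicity_shifts: Mapping[str, float] = field(default_factory=dict)
    bias: bool = False
    bias_strength: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        if self.or_allele <= 0:
            raise ValidationError("or_allele must be positive")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        lo, hi = (self.maf, self.maf) if isinstance(self.maf, float) else self.maf
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("risk-allele frequency must lie in (0, 1)")


def _draw_size(spec: SizeSpec, index: int, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    if isinstance(spec, tuple) and len(spec) == 2:
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec[index])


def _draw_freq(spec: FreqSpec, rng: np.random.Generator) -> float:
    if isinstance(spec, float):
        return spec
    lo, hi = spec
    return float(rng.uniform(lo, hi))


def _draw_label(probs: Mapping[str, float], rng: np.random.Generator) -> str:
    labels = list(probs)
    p = np.array([probs[l] for l in labels], dtype=float)
    return labels[int(rng.choice(len(labels), p=p / p.sum()))]


def _genotype_draw(n: int, probs: np.ndarray, rng: np.random.Generator) -> GenotypeCounts:
    cc, ct, tt = rng.multinomial(n, probs)
    return GenotypeCounts(int(cc), int(ct), int(tt))


def _simulate_one(sc: SimScenario, index: int) -> tuple[Study, np.random.Generator]:
    """Generate study ``index``; returns the study and its (advanced) rng
    so the bias mechanism can append a retention draw to the same stream."""
    rng = np.random.default_rng([sc.seed, index])
    q = _draw_freq(sc.maf, rng)
    ethnicity = _draw_label(sc.ethnicity_probs, rng)
    soc = _draw_label(sc.soc_probs, rng)
    n_cases = _draw_size(sc.case_sizes, index, rng)
    n_controls = _draw_size(sc.control_sizes, index, rng)

    log_or = math.log(sc.or_allele) + sc.ethnicity_shifts.get(ethnicity, 0.0)
    log_or += float(rng.normal(0.0, sc.tau)) if sc.tau > 0 else 0.0
    r = math.exp(log_or)

    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    controls = _genotype_draw(n_controls, hwe, rng)
    case_probs = hwe * np.array([1.0, r, r * r])
    cases = _genotype_draw(n_cases, case_probs / case_probs.sum(), rng)
    study = Study(
        study_id=f"sim{index:03d}",
        year=2000 + index % 25,
        ethnicity=Ethnicity(ethnicity),
        soc=SourceOfControls(soc),
        cases=cases,
        controls=controls,
    )
    return study, rng


def simulate_studies(sc: SimScenario) -> StudySet:
    """Generate ``sc.n_studies`` studies; byte-identical for equal seeds."""
    return StudySet(tuple(_simulate_one(sc, i)[0] for i in range(sc.n_studies)))


def simulate_biased(sc: SimScenario) -> StudySet:
    """Generate studies and, when ``sc.bias`` is on, retain each with
    probability Phi(bias_strength * z_i), z_i the study's one-sided
    allele-model z score — small null/negative studies are suppressed.
    With ``sc.bias`` off this returns exactly :func:`simulate_studies`."""
    kept = []
    for i in range(sc.n_studies):
        study, rng = _simulate_one(sc, i)
        if sc.bias:
            eff = estimate_effect(make_2x2(study, GeneticModel.ALLELE))
            p_keep = float(stats.norm.cdf(sc.bias_strength * eff.log_or / eff.se))
            if rng.uniform() >= p_keep:
                continue
        kept.append(study)
    return StudySet(tuple(kept))


def fixture_like_scenario(or_allele: float = 1.0, tau: float = 0.0, seed: int = 0) -> SimScenario:
    """A scenario sized like the bundled 13-study prostate-cancer dataset:
    its exact case/control group sizes, a risk-allele frequency range
    matching its control frequencies, and its moderator proportions."""
    from .study_io import load_fixture

    fx = load_fixture()
    return SimScenario(
        n_studies=len(fx),
        case_sizes=[s.cases.n for s in fx],
        control_sizes=[s.controls.n for s in fx],
        maf=(0.33, 0.45),
        or_allele=or_allele,
        tau=tau,
        ethnicity_probs={"Caucasian": 9 / 13, "Asian": 2 / 13, "African-American": 1 / 13, "Mixed": 1 / 13},
        soc_probs={"HB": 5 / 13, "PB": 8 / 13},
        seed=seed,
    )
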