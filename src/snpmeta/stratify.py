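"""Subgroup analyses and leave-one-out sensitivity analysis.

Subgroups stratify on a study-level moderator (ethnicity or source of
controls).  By default each stratum is pooled under the model the
heterogeneity rule selects for the *full* study set (``selection =
"inherit"``) — the convention of the classic meta commands, which carry
one model through a stratified run; ``selection = "per-stratum"``
re-applies the rule within each stratum instead.  A stratum of one study
reports the study's own crude estimate unchanged under either setting.

Leave-one-out re-pools the remaining k-1 studies after omitting each study
in turn; a stable meta-analysis keeps its conclusion in every row.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InsufficientStudiesError, ValidationError
from .genetic_models import GeneticModel, estimate_effect, make_2x2, study_effects
from .pooling import (
    PooledResult,
    PoolingModel,
    analyze,
    cochran_q,
    pool_fixed,
    pool_random_dl,
    select_model,
    single_study_result,
)
from .study_io import Ethnicity, SourceOfControls, StudySet

__all__ = ["SubgroupResult", "LeaveOneOutRow", "subgroup_analysis", "leave_one_out", "FACTORS"]

#: Supported stratification factors and their level orderings.
FACTORS = {
    "ethnicity": tuple(Ethnicity),
    "soc": tuple(SourceOfControls),
}


@dataclass(frozen=True)
class SubgroupResult:
    factor: str
    level: str
    k: int
    result: PooledResult
    study_ids: tuple[str, ...]


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_study_id: str
    result: PooledResult


def subgroup_analysis(
    studies: StudySet,
    model: GeneticModel,
    factor: str,
    het_p: float = 0.1,
    i2_threshold: float = 50.0,
    selection: str = "inherit",
) -> list[SubgroupResult]:
    """Pool each observed level of ``factor`` separately.

    Levels appear in the canonical vocabulary order (Caucasian, Asian,
    African-American, Mixed; HB, PB); unobserved levels are omitted.
    ``selection`` is ``"inherit"`` (pool every stratum under the model
    chosen for the full set) or ``"per-stratum"`` (re-run the selection
    rule inside each stratum).
    """
    if factor not in FACTORS:
        raise ValidationError(f"unknown stratification factor {factor!r}; expected one of {sorted(FACTORS)}")
    if selection not in ("inherit", "per-stratum"):
        raise ValidationError(f"unknown selection mode {selection!r}")
    inherited: PoolingModel | None = None
    if selection == "inherit" and len(studies) >= 2:
        effects = [e for _, e in study_effects(studies, model)]
        _, p_q, i2 = cochran_q(effects)
        inherited = select_model(p_q, i2, het_p, i2_threshold)
    results: list[SubgroupResult] = []
    for level in FACTORS[factor]:
        members = [s for s in studies if getattr(s, factor) is level]
        if not members:
            continue
        stratum = StudySet(tuple(members))
        if len(stratum) == 1:
            pooled = single_study_result(estimate_effect(make_2x2(stratum[0], model)))
        elif inherited is not None:
            stratum_effects = [e for _, e in study_effects(stratum, model)]
            if inherited is PoolingModel.RANDOM:
                pooled = pool_random_dl(stratum_effects)
            else:
                pooled = pool_fixed(stratum_effects)
        else:
            pooled = analyze(stratum, model, het_p, i2_threshold)
        results.append(
            SubgroupResult(
                factor=factor,
                level=level.value,
                k=len(stratum),
                result=pooled,
                study_ids=stratum.ids,
            )
        )
    return results


def leave_one_out(
    studies: StudySet,
    model: GeneticModel,
    het_p: float = 0.1,
    i2_threshold: float = 50.0,
) -> list[LeaveOneOutRow]:
    """Re-pool the study set k times, omitting each study once.

    Model selection is re-run on every reduced set.  Requires k >= 3 so
    each reduced set is still poolable.
    """
    if len(studies) < 3:
        raise InsufficientStudiesError("leave-one-out needs at least 3 studies")
    return [
        LeaveOneOutRow(
            omitted_study_id=sid,
            result=analyze(studies.drop(sid), model, het_p, i2_threshold),
        )
        for sid in studies.ids
    ]
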