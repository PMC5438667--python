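"""Full-pipeline driver and structured report.

:func:`run_pipeline` executes the whole analysis on a study table —
HWE screening, pooled analysis under each genetic-model contrast,
subgroup analyses, leave-one-out sensitivity, publication-bias tests,
meta-regression and post-hoc power — and returns one JSON-serialisable
dictionary mirroring the standard reporting tables of an association
meta-analysis (per-study forest rows, pooled estimates, heterogeneity,
funnel series).  Stages whose study-count preconditions fail are skipped
with an explicit note instead of aborting the run.
"""

from __future__ import annotations

import hashlib
import math
from importlib import metadata
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .errors import DegenerateDesignError, InsufficientStudiesError
from .genetic_models import GeneticModel, study_effects
from .hwe import hwe_test
from .meta_regression import MetaRegResult, meta_regress
from .pooling import PooledResult, analyze
from .power import meta_power
from .publication_bias import begg_test, egger_test, funnel_series
from .stratify import leave_one_out, subgroup_analysis
from .study_io import StudySet, load_fixture, read_studies, totals

__all__ = ["run_pipeline", "export_forest", "pooled_to_dict"]

_MODEL_KEYS = {
    GeneticModel.ALLELE: "allele",
    GeneticModel.DOMINANT: "dominant",
    GeneticModel.RECESSIVE: "recessive",
}


def _nan_to_none(x: float) -> float | None:
    return None if isinstance(x, float) and math.isnan(x) else x


def pooled_to_dict(r: PooledResult) -> dict[str, Any]:
    return {
        "model_used": r.model_used.value,
        "or": r.pooled_or,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "log_or": r.pooled_log_or,
        "se_log": r.se_log,
        "z": r.z,
        "p_value": r.p_value,
        "q": r.q,
        "p_q": _nan_to_none(r.p_q),
        "i2": r.i2,
        "tau2": r.tau2,
        "k": r.k,
        "weights": list(r.weights),
    }


def _metareg_to_dict(m: MetaRegResult) -> dict[str, Any]:
    return {
        "coefficients": [
            {"name": c.name, "estimate": c.estimate, "se": c.se, "z": c.z, "p_value": c.p_value}
            for c in m.coefficients
        ],
        "residual_tau2": m.residual_tau2,
        "omnibus_chi2": m.omnibus_chi2,
        "omnibus_p": _nan_to_none(m.omnibus_p),
        "k": m.k,
        "n_params": m.n_params,
        "reference_levels": dict(m.reference_levels),
    }


def export_forest(studies: StudySet, model: GeneticModel, pooled: PooledResult) -> pd.DataFrame:
    """Forest-plot data: one row per study (OR, CI, relative weight in %)
    plus a final pooled 'diamond' row."""
    rows = []
    for (sid, eff), w in zip(study_effects(studies, model), pooled.weights):
        rows.append(
            {
                "study_id": sid,
                "or": eff.or_,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "weight_pct": 100.0 * w,
            }
        )
    rows.append(
        {
            "study_id": f"Pooled ({pooled.model_used.value})",
            "or": pooled.pooled_or,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def _resolve_input(source: str | Path | StudySet) -> tuple[StudySet, dict[str, Any]]:
    if isinstance(source, StudySet):
        return source, {"source": "<in-memory>", "sha256": None}
    if str(source) == "fixture":
        return load_fixture(), {"source": "fixture", "sha256": None}
    path = Path(source)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return read_studies(path), {"source": str(path), "sha256": digest}


def run_pipeline(
    source: str | Path | StudySet = "fixture",
    models: Sequence[GeneticModel] = tuple(GeneticModel),
    factors: Sequence[str] = ("ethnicity", "soc"),
    loo: bool = True,
    bias: bool = True,
    metareg: bool = True,
    power_or: float | None = None,
    alpha: float = 0.05,
    het_p: float = 0.1,
    i2_threshold: float = 50.0,
    hwe_threshold: float = 0.05,
) -> dict[str, Any]:
    """Run the full meta-analysis pipeline and return the report dict.

    ``power_or`` is the detectable odds ratio for the post-hoc power
    computation; when None the dominant-model pooled OR of this run
    (rounded to 2 decimals, the conventional headline figure) is used.
    """
    studies, provenance = _resolve_input(source)
    n_cases, n_controls, k = totals(studies)
    notes: list[str] = []
    try:
        version = metadata.version("snpmeta")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"

    report: dict[str, Any] = {
        "input": {**provenance, "n_studies": k, "total_cases": n_cases, "total_controls": n_controls},
        "package_version": version,
        "parameters": {
            "alpha": alpha,
            "het_p": het_p,
            "i2_threshold": i2_threshold,
            "hwe_threshold": hwe_threshold,
        },
    }

    report["hwe"] = [
        {
            "study_id": s.study_id,
            "chi2": res.chi2,
            "p_value": res.p_value,
            "in_hwe": res.in_hwe,
            "monomorphic": res.monomorphic,
        }
        for s in studies
        for res in [hwe_test(s.controls, hwe_threshold)]
    ]

    report["models"] = {}
    pooled_by_model: dict[GeneticModel, PooledResult] = {}
    for gm in models:
        key = _MODEL_KEYS[gm]
        if k < 2:
            notes.append(f"{key}: insufficient studies for pooling (k={k})")
            report["models"][key] = None
            continue
        pooled = analyze(studies, gm, het_p, i2_threshold)
        pooled_by_model[gm] = pooled
        forest = export_forest(studies, gm, pooled)
        report["models"][key] = {
            "contrast": gm.value,
            "pooled": pooled_to_dict(pooled),
            "forest": forest.to_dict(orient="records"),
        }

    report["subgroups"] = {}
    for gm in models:
        key = _MODEL_KEYS[gm]
        report["subgroups"][key] = {}
        for factor in factors:
            report["subgroups"][key][factor] = [
                {
                    "level": sg.level,
                    "k": sg.k,
                    "study_ids": list(sg.study_ids),
                    "pooled": pooled_to_dict(sg.result),
                }
                for sg in subgroup_analysis(studies, gm, factor, het_p, i2_threshold)
            ]

    report["leave_one_out"] = {}
    if loo:
        for gm in models:
            key = _MODEL_KEYS[gm]
            try:
                report["leave_one_out"][key] = [
                    {"omitted": row.omitted_study_id, "pooled": pooled_to_dict(row.result)}
                    for row in leave_one_out(studies, gm, het_p, i2_threshold)
                ]
            except InsufficientStudiesError as exc:
                notes.append(f"leave-one-out ({key}) skipped: {exc}")
                report["leave_one_out"][key] = None

    report["publication_bias"] = {}
    if bias:
        for gm in models:
            key = _MODEL_KEYS[gm]
            effects = study_effects(studies, gm)
            plain = [e for _, e in effects]
            try:
                egger = egger_test(plain)
                begg = begg_test(plain)
            except InsufficientStudiesError as exc:
                notes.append(f"publication bias ({key}) skipped: {exc}")
                report["publication_bias"][key] = None
                continue
            report["publication_bias"][key] = {
                "egger": {
                    "intercept": egger.intercept,
                    "intercept_se": egger.intercept_se,
                    "slope": egger.slope,
                    "t": egger.t_stat,
                    "p_value": egger.p_value,
                },
                "begg": {
                    "s": begg.kendall_s,
                    "tau": begg.tau,
                    "z": begg.z,
                    "p_value": begg.p_value,
                },
                "funnel": funnel_series(effects).to_dict(orient="records"),
            }

    report["meta_regression"] = {}
    if metareg:
        for gm in models:
            key = _MODEL_KEYS[gm]
            effects = [e for _, e in study_effects(studies, gm)]
            mods = {
                "ethnicity": [s.ethnicity.value for s in studies],
                "soc": [s.soc.value for s in studies],
            }
            fits: dict[str, Any] = {}
            # factors jointly and one at a time, since either view can
            # implicate (or clear) a moderator
            wanted = [tuple(factors)] + [(f,) for f in factors]
            for combo in wanted:
                name = "+".join(combo)
                try:
                    fits[name] = _metareg_to_dict(meta_regress(effects, mods, list(combo)))
                except (InsufficientStudiesError, DegenerateDesignError) as exc:
                    notes.append(f"meta-regression ({key}, {name}) skipped: {exc}")
                    fits[name] = None
            report["meta_regression"][key] = fits

    power_target = power_or
    if power_target is None and GeneticModel.DOMINANT in pooled_by_model:
        power_target = round(pooled_by_model[GeneticModel.DOMINANT].pooled_or, 2)
    if power_target is not None:
        pw = meta_power(studies, or_=power_target, alpha=alpha)
        report["power"] = {
            "power": pw.power,
            "alpha": pw.alpha,
            "assumed_or": pw.assumed_or,
            "exposure_freq_controls": pw.exposure_freq_controls,
            "n_cases": pw.n_cases,
            "n_controls": pw.n_controls,
        }
    else:
        report["power"] = None
        notes.append("power skipped: no pooled dominant OR and no assumed OR given")

    report["notes"] = notes
    return report
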