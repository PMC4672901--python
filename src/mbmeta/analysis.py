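"""Wiring of the per-record effect sizes into the standard analyses.

Six random-effects meta-analyses cover the rutabaga data (the mutant
genotype groups plus one per lobe-restoration category) and three cover
the shibire data (the heat-effect controls plus the two inactivation
categories with more than one experiment); the single-experiment gamma
inactivation is reported unpooled.
"""

from __future__ import annotations

from typing import Optional

from .corpus import (
    Dataset,
    assign_lobe_category,
    heat_control_subgroup,
    rut_mutant_subgroup,
)
from .effects import (
    EffectSize,
    effect_from_record,
    heat_adjusted,
    rescue_relative,
    to_learning_scale,
)
from .meta import MetaResult, pool_random_effects, subgroup_analysis

__all__ = [
    "RUT_ANALYSES",
    "SHI_ANALYSES",
    "run_meta_analyses",
    "learning_summary",
]

RUT_ANALYSES = (
    "rut_mutants",
    "rut_rescue_alphabeta",
    "rut_rescue_alphaprime_betaprime",
    "rut_rescue_gamma",
    "rut_rescue_alphabeta_gamma",
    "rut_rescue_all_lobes",
)
SHI_ANALYSES = (
    "heat_controls",
    "shi_alphabeta",
    "shi_alphabeta_gamma",
    "shi_gamma",
)

_LOBES = ("alphabeta", "alphaprime_betaprime", "gamma", "alphabeta_gamma", "all_lobes")


def _pool(ds: Dataset, pred, grouping_fn, scale: str) -> Optional[MetaResult]:
    records = [r for r in ds.records if pred(r)]
    if not records:
        return None
    estimates = [effect_from_record(r, scale=scale) for r in records]
    if len(estimates) == 1:
        return pool_random_effects(estimates)
    return subgroup_analysis(estimates, [grouping_fn(r) for r in records])


def run_meta_analyses(
    ds: Dataset,
    analysis_set: str = "both",
    reassign_201Y: bool = False,
    scale: str = "percent_change",
) -> dict[str, MetaResult]:
    """Run the named random-effects analyses present in the dataset.

    Lobe-restoration and inactivation analyses subgroup by driver line;
    the mutant and heat-control analyses subgroup by genotype class.
    Analyses with no matching records are omitted from the result.
    """
    if analysis_set not in ("rut", "shi", "both"):
        raise ValueError(f"unknown analysis set {analysis_set!r}")
    out: dict[str, MetaResult] = {}

    def lobe_of(r):
        return assign_lobe_category(r, reassign_201Y=reassign_201Y)

    if analysis_set in ("rut", "both"):
        res = _pool(
            ds,
            lambda r: r.intervention == "rut_mutant",
            rut_mutant_subgroup,
            scale,
        )
        if res:
            out["rut_mutants"] = res
        for lobe in _LOBES:
            res = _pool(
                ds,
                lambda r, lobe=lobe: r.intervention == "rut_rescue"
                and lobe_of(r) == lobe,
                lambda r: r.driver or "?",
                scale,
            )
            if res:
                out[f"rut_rescue_{lobe}"] = res
    if analysis_set in ("shi", "both"):
        res = _pool(
            ds,
            lambda r: r.intervention == "heat_control",
            heat_control_subgroup,
            scale,
        )
        if res:
            out["heat_controls"] = res
        for lobe in _LOBES:
            res = _pool(
                ds,
                lambda r, lobe=lobe: r.intervention == "shi_inactivation"
                and lobe_of(r) == lobe,
                lambda r: r.driver or "?",
                scale,
            )
            if res:
                out[f"shi_{lobe}"] = res
    return out


def learning_summary(
    results: dict[str, MetaResult],
    mutant_ref: Optional[float] = None,
    heat_ref: Optional[float] = None,
) -> list[dict]:
    """Summarise pooled percentage changes on the learning scale.

    The rescue column is relative to the pooled mutant learning level
    (defaulting to the in-set ``rut_mutants`` result); the heat-adjusted
    column is relative to the pooled heat-control learning level.
    """
    if mutant_ref is None and "rut_mutants" in results:
        mutant_ref = 100.0 + results["rut_mutants"].pooled.estimate
    if heat_ref is None and "heat_controls" in results:
        heat_ref = 100.0 + results["heat_controls"].pooled.estimate
    rows = []
    for name, res in results.items():
        pooled = res.pooled
        if pooled.scale != "percent_change":
            raise ValueError("learning summary requires percent_change analyses")
        learning = to_learning_scale(pooled)
        row = {
            "analysis": name,
            "k": res.k,
            "n_exp": pooled.n_exp,
            "n_ctrl": pooled.n_ctrl,
            "percent_change": pooled.estimate,
            "se": pooled.se,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "learning_percent": learning.estimate,
            "i2": res.i2,
            "i2_subgroup": res.i2_subgroup,
            "tau2": res.tau2,
        }
        if name.startswith("rut_rescue") and mutant_ref is not None:
            row["rescue_percent"] = rescue_relative(learning, mutant_ref).estimate
        if name.startswith("shi_") and heat_ref is not None:
            row["heat_adjusted_percent"] = heat_adjusted(learning, heat_ref).estimate
        rows.append(row)
    return rows
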