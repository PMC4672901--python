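"""Inverse-variance random-effects pooling with subgroup heterogeneity.

The between-study variance tau^2 uses the DerSimonian-Laird moment
estimator (the Review-Manager default); each subgroup receives its own
tau^2. Between-subgroup heterogeneity is the Q decomposition
Q_between = Q_total - sum(Q_within) with its own I^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .effects import EffectSize

__all__ = [
    "MetaResult",
    "ForestRow",
    "InsufficientDataError",
    "dl_tau2",
    "pool_random_effects",
    "subgroup_analysis",
    "welch_t",
    "forest_table",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class MetaResult:
    pooled: EffectSize
    tau2: float
    q: float
    df: int
    i2: float
    k: int
    estimates: list[EffectSize] = field(default_factory=list, repr=False)
    subgroups: list[tuple[str, "MetaResult"]] = field(default_factory=list)
    q_between: Optional[float] = None
    i2_subgroup: Optional[float] = None


def _fixed_effect_q(estimates: Sequence[EffectSize]) -> tuple[float, float, float]:
    """Return (Q, sum of FE weights, FE pooled mean)."""
    w = [1.0 / e.variance for e in estimates]
    sw = sum(w)
    mean = sum(wi * e.estimate for wi, e in zip(w, estimates)) / sw
    q = sum(wi * (e.estimate - mean) ** 2 for wi, e in zip(w, estimates))
    return q, sw, mean


def _check_variances(estimates: Sequence[EffectSize]) -> None:
    for e in estimates:
        if e.variance <= 0:
            raise InsufficientDataError(
                f"estimate {e.source or e.estimate} has zero variance; "
                f"inverse-variance weights are degenerate"
            )


def dl_tau2(estimates: Sequence[EffectSize]) -> float:
    """DerSimonian-Laird moment estimate of between-study variance.

    tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w) and
    fixed-effect weights w = 1/variance.
    """
    if len(estimates) < 2:
        raise InsufficientDataError(
            f"need >= 2 estimates for tau^2, got {len(estimates)}"
        )
    _check_variances(estimates)
    q, sw, _ = _fixed_effect_q(estimates)
    w = [1.0 / e.variance for e in estimates]
    c = sw - sum(wi**2 for wi in w) / sw
    df = len(estimates) - 1
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def _i2_from_q(q: float, df: int) -> float:
    if q <= 0 or df < 0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def pool_random_effects(estimates: Sequence[EffectSize]) -> MetaResult:
    """Random-effects pooled estimate with DL tau^2 and I^2.

    A single estimate passes through unchanged (tau^2 = 0).
    """
    estimates = list(estimates)
    if not estimates:
        raise InsufficientDataError("no estimates to pool")
    scale = estimates[0].scale
    if any(e.scale != scale for e in estimates):
        raise ValueError("cannot pool estimates on mixed scales")
    if len(estimates) == 1:
        e = estimates[0]
        return MetaResult(
            pooled=e, tau2=0.0, q=0.0, df=0, i2=0.0, k=1, estimates=estimates
        )
    _check_variances(estimates)
    tau2 = dl_tau2(estimates)
    q, _, _ = _fixed_effect_q(estimates)
    df = len(estimates) - 1
    w_star = [1.0 / (e.variance + tau2) for e in estimates]
    sw = sum(w_star)
    mean = sum(wi * e.estimate for wi, e in zip(w_star, estimates)) / sw
    pooled = EffectSize(
        estimate=mean,
        se=1.0 / math.sqrt(sw),
        scale=scale,
        n_exp=sum(e.n_exp for e in estimates),
        n_ctrl=sum(e.n_ctrl for e in estimates),
    )
    return MetaResult(
        pooled=pooled,
        tau2=tau2,
        q=q,
        df=df,
        i2=_i2_from_q(q, df),
        k=len(estimates),
        estimates=estimates,
    )


def subgroup_analysis(
    estimates: Sequence[EffectSize], grouping: Sequence[str]
) -> MetaResult:
    """Pool overall and within each subgroup, with between-group Q and I^2.

    Subgroups keep input order of first appearance; singleton subgroups
    are reported without pooling.
    """
    estimates = list(estimates)
    grouping = list(grouping)
    if len(estimates) != len(grouping):
        raise ValueError("one label per estimate required")
    if not estimates:
        raise InsufficientDataError("no estimates to pool")
    overall = pool_random_effects(estimates)
    labels: list[str] = []
    members: dict[str, list[EffectSize]] = {}
    for label, e in zip(grouping, estimates):
        if label not in members:
            labels.append(label)
            members[label] = []
        members[label].append(e)
    subgroups = [(label, pool_random_effects(members[label])) for label in labels]
    q_within = sum(res.q for _, res in subgroups)
    q_between = max(0.0, overall.q - q_within)
    g = len(labels)
    overall.subgroups = subgroups
    overall.q_between = q_between
    overall.i2_subgroup = _i2_from_q(q_between, g - 1)
    return overall


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sample t-test with unequal variances (Satterthwaite df)."""
    from scipy import stats

    a = list(map(float, group_a))
    b = list(map(float, group_b))
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sa2, sb2 = va / na, vb / nb
    if sa2 + sb2 == 0:
        return {"t": 0.0, "df": float(na + nb - 2), "p": 1.0}
    t = (ma - mb) / math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": t, "df": df, "p": p}


@dataclass(frozen=True)
class ForestRow:
    kind: str  # "study" | "subgroup" | "overall"
    label: str
    estimate: float
    ci_low: float
    ci_high: float
    weight_pct: Optional[float] = None
    subgroup: Optional[str] = None


def forest_table(meta: MetaResult) -> list[ForestRow]:
    """Flatten a meta-analysis into ordered forest-plot rows.

    Study rows are grouped under their subgroup diamond (input order);
    per-study weights are random-effects weights normalised to 100%
    within the overall pooled set.
    """
    tau2 = meta.tau2
    w = [1.0 / (e.variance + tau2) if e.variance + tau2 > 0 else 0.0 for e in meta.estimates]
    sw = sum(w) or 1.0
    weights = {id(e): 100.0 * wi / sw for wi, e in zip(w, meta.estimates)}

    def study_row(e: EffectSize, subgroup: Optional[str]) -> ForestRow:
        label = "/".join(map(str, e.source[:3])) if e.source else f"{e.estimate:+.1f}"
        return ForestRow(
            "study", label, e.estimate, e.ci_low, e.ci_high,
            weight_pct=weights.get(id(e)), subgroup=subgroup,
        )

    rows: list[ForestRow] = []
    if meta.subgroups:
        for label, sub in meta.subgroups:
            rows.extend(study_row(e, label) for e in sub.estimates)
            rows.append(
                ForestRow(
                    "subgroup", label, sub.pooled.estimate,
                    sub.pooled.ci_low, sub.pooled.ci_high,
                    weight_pct=sum(weights.get(id(e), 0.0) for e in sub.estimates),
                    subgroup=label,
                )
            )
    else:
        rows.extend(study_row(e, None) for e in meta.estimates)
    p = meta.pooled
    rows.append(ForestRow("overall", "Overall", p.estimate, p.ci_low, p.ci_high, weight_pct=100.0))
    return rows
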