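"""Per-experiment effect sizes on the raw-PI and percentage-change scales.

The percentage change of the experimental arm relative to its control
uses the delta-method approximation for the standard error of a ratio of
means. Conversions to the learning / rescue / heat-adjusted scales are
pure shifts and preserve the confidence-interval width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "EffectSize",
    "ScaleError",
    "Z_95",
    "percent_change",
    "raw_change",
    "to_learning_scale",
    "rescue_relative",
    "heat_adjusted",
    "effect_from_record",
]

Z_95 = 1.96  # normal 95% CI multiplier

SCALES = (
    "raw_pi",
    "percent_change",
    "learning_percent",
    "rescue_percent",
    "heat_adjusted_percent",
)


class ScaleError(ValueError):
    """Raised when an operation receives an effect on the wrong scale."""


@dataclass(frozen=True)
class EffectSize:
    estimate: float
    se: float
    scale: str
    n_exp: int = 0
    n_ctrl: int = 0
    source: Optional[tuple] = None

    def __post_init__(self):
        if self.se < 0:
            raise ValueError(f"se must be >= 0, got {self.se}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def ci_low(self) -> float:
        return self.estimate - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z_95 * self.se


def percent_change(
    m_exp: float,
    se_exp: float,
    m_ctrl: float,
    se_ctrl: float,
    n_exp: int = 0,
    n_ctrl: int = 0,
    source: Optional[tuple] = None,
) -> EffectSize:
    """Percentage change of the experimental mean relative to control.

    estimate = 100 * (m_exp / m_ctrl - 1); the SE is the delta-method
    approximation for a ratio of independent means,
    100 * |m_exp / m_ctrl| * sqrt(cv_exp^2 + cv_ctrl^2).
    """
    if se_exp < 0 or se_ctrl < 0:
        raise ValueError("standard errors must be >= 0")
    if m_ctrl == 0:
        raise ZeroDivisionError("control mean is zero: percentage change undefined")
    if m_exp == 0 and se_exp > 0:
        raise ValueError(
            "experimental mean is zero with positive SE: delta-method CV "
            "degenerate; use raw_change instead"
        )
    ratio = m_exp / m_ctrl
    cv2 = 0.0
    if m_exp != 0:
        cv2 += (se_exp / m_exp) ** 2
    cv2 += (se_ctrl / m_ctrl) ** 2
    se = 100.0 * abs(ratio) * math.sqrt(cv2)
    return EffectSize(
        estimate=100.0 * (ratio - 1.0),
        se=se,
        scale="percent_change",
        n_exp=n_exp,
        n_ctrl=n_ctrl,
        source=source,
    )


def raw_change(
    m_exp: float,
    se_exp: float,
    m_ctrl: float,
    se_ctrl: float,
    n_exp: int = 0,
    n_ctrl: int = 0,
    source: Optional[tuple] = None,
) -> EffectSize:
    """Raw difference in PI between arms; SE adds in quadrature."""
    if se_exp < 0 or se_ctrl < 0:
        raise ValueError("standard errors must be >= 0")
    return EffectSize(
        estimate=m_exp - m_ctrl,
        se=math.hypot(se_exp, se_ctrl),
        scale="raw_pi",
        n_exp=n_exp,
        n_ctrl=n_ctrl,
        source=source,
    )


def _require_scale(es: EffectSize, scale: str) -> None:
    if es.scale != scale:
        raise ScaleError(f"expected scale {scale!r}, got {es.scale!r}")


def to_learning_scale(es: EffectSize) -> EffectSize:
    """Express a percentage change as learning relative to wild type (100 + change)."""
    _require_scale(es, "percent_change")
    return replace(es, estimate=100.0 + es.estimate, scale="learning_percent")


def rescue_relative(es: EffectSize, mutant_ref: float) -> EffectSize:
    """Rescue above the mutant baseline: learning minus the mutant learning level."""
    _require_scale(es, "learning_percent")
    return replace(es, estimate=es.estimate - mutant_ref, scale="rescue_percent")


def heat_adjusted(es: EffectSize, heat_ref: float) -> EffectSize:
    """Learning change relative to the pooled heat-only control level."""
    _require_scale(es, "learning_percent")
    return replace(es, estimate=es.estimate - heat_ref, scale="heat_adjusted_percent")


def effect_from_record(record, scale: str = "percent_change") -> EffectSize:
    """Compute the effect size for a corpus record carrying PI summaries."""
    vals = (
        record.pi_exp_mean,
        record.pi_exp_sem,
        record.pi_ctrl_mean,
        record.pi_ctrl_sem,
    )
    if any(v is None for v in vals):
        raise ValueError(
            f"record {record.study_id}/{record.figure_panel}/"
            f"{record.genotype_exp} has no PI summaries; the packaged "
            f"table fixture prints iteration counts only"
        )
    fn = percent_change if scale == "percent_change" else raw_change
    return fn(
        *vals,
        n_exp=record.n_exp,
        n_ctrl=record.n_ctrl,
        source=record.key,
    )
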