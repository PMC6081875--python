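"""Protocol- and cohort-level comparison statistics.

The hybrid protocol is validated against the reference protocol with

* percentage contributions of each dose constituent to the total,
* absolute percentage deviations |(D_HP - D_RP) / D_RP| * 100,
* the TAC-parameter identity: for mono-exponential curves the product of the
  intercept ratio and the half-life ratio equals the TIA ratio, so perfect
  protocol agreement means (A0_RP/A0_HP) * (T_RP/T_HP) = 1,
* cohort medians with (min-max) ranges, and
* Pearson correlation between paired reference and hybrid doses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, UndefinedCorrelationError
from .tac import MonoExpFit, integrate_to_infinity

__all__ = [
    "percentage_contribution",
    "percentage_deviation",
    "tac_parameter_ratios",
    "cohort_summary",
    "pearson_correlation",
    "TacRatios",
]


def percentage_contribution(component_dose: float, total_dose: float) -> float:
    """Constituent share of the total marrow dose, in percent."""
    if total_dose <= 0:
        raise DomainError(f"total dose must be positive, got {total_dose}")
    return 100.0 * component_dose / total_dose


def percentage_deviation(d_hp: float, d_rp: float) -> float:
    """Absolute percentage deviation of a hybrid estimate from the reference."""
    if d_rp <= 0:
        raise DomainError(f"reference dose must be positive, got {d_rp}")
    return 100.0 * abs(d_hp - d_rp) / d_rp


@dataclass(frozen=True)
class TacRatios:
    """Reference-to-hybrid TAC parameter ratios and their product."""

    a0_ratio: float
    half_life_ratio: float
    product: float
    tia_ratio: float


def tac_parameter_ratios(fit_rp: MonoExpFit, fit_hp: MonoExpFit) -> TacRatios:
    """Reference-to-hybrid intercept and half-life ratios.

    For mono-exponentials A~ = A0 * T_half / ln 2, so the product of the two
    ratios equals the TIA ratio exactly; it is 1 iff the two TIAs agree.
    """
    a0_ratio = fit_rp.amplitude_A0 / fit_hp.amplitude_A0
    t_ratio = fit_rp.half_life / fit_hp.half_life
    tia_ratio = integrate_to_infinity(fit_rp) / integrate_to_infinity(fit_hp)
    return TacRatios(
        a0_ratio=a0_ratio,
        half_life_ratio=t_ratio,
        product=a0_ratio * t_ratio,
        tia_ratio=tia_ratio,
    )


def cohort_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max) of a cohort metric.

    Median of an even-length cohort is the mean of the two central order
    statistics.  Rounding is a display concern, never applied here.
    """
    if len(values) == 0:
        raise DomainError("cannot summarise an empty cohort")
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r and two-sided p (t-transform, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("correlation needs two equal-length series of >= 3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
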