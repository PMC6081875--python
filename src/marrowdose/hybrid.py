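"""Hybrid single-planar + sequential-SPECT protocol.

The reference protocol needs three whole-body planar scans to fit the
whole-body washout.  The hybrid protocol replaces them with a single planar
acquisition: the effective decay constant is instead taken from the three
abdominal SPECT field-of-view totals (organs and tumours included, nothing
subtracted), and the resulting mono-exponential is anchored at the
whole-body activity A_WB(t*) of the one planar image,

    A_WB,pseudo(t) = A_WB(t*) * exp(-lambda_SPECT * (t - t*)),

whose integral from zero to infinity is the pseudo-whole-body TIA

    A~_WB,pseudo = A_WB(t*) * exp(lambda_SPECT * t*) / lambda_SPECT.

Only the remainder-of-body constituent changes; blood and organ doses are
identical to the reference report.  The anchor time t* is one of the
acquired planar times (24, 48 or 72 h), labelled HP24/HP48/HP72.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .dosimetry import (
    DoseReport,
    PatientContext,
    PhantomReference,
    SourceActivitySet,
    compute_dose_report,
)
from .errors import ConfigurationError, DomainError, NonIntegrableError
from .tac import LN2, ActivitySample, MonoExpFit, fit_monoexp

__all__ = [
    "HP_LABELS",
    "HybridBasePoint",
    "AbdominalKinetics",
    "abdominal_decay_constant",
    "pseudo_wb_tia",
    "hybrid_bm_dose",
]

#: Fixed protocol labels keyed by anchor time (h post-injection).
HP_LABELS = {24: "HP24", 48: "HP48", 72: "HP72"}


@dataclass(frozen=True)
class HybridBasePoint:
    """Anchor of the pseudo-whole-body curve: one calibrated planar activity."""

    t_star_h: float
    a_wb_bq: float

    def __post_init__(self):
        if self.t_star_h < 0:
            raise DomainError(f"base-point time must be >= 0 h, got {self.t_star_h}")
        if self.a_wb_bq <= 0:
            raise DomainError(f"base-point activity must be positive, got {self.a_wb_bq}")


@dataclass(frozen=True)
class AbdominalKinetics:
    """Effective washout of the abdominal SPECT field of view."""

    decay_lambda: float
    source_fit: MonoExpFit | None = None

    def __post_init__(self):
        if self.decay_lambda <= 0:
            raise DomainError("abdominal decay constant must be positive")

    @property
    def half_life_h(self) -> float:
        return LN2 / self.decay_lambda


def abdominal_decay_constant(
    spect_totals: Sequence[ActivitySample], min_points: int = 3
) -> AbdominalKinetics:
    """Mono-exponential fit to the sequential SPECT field-of-view totals.

    All organs and all tumours are part of the totals, mirroring how the
    whole-body curve of the reference protocol is fitted.
    """
    fit = fit_monoexp(spect_totals, min_points=min_points)
    return AbdominalKinetics(decay_lambda=fit.decay_lambda, source_fit=fit)


def pseudo_wb_tia(base: HybridBasePoint, kin: AbdominalKinetics) -> float:
    """Pseudo-whole-body TIA (Bq h): A_WB(t*) * exp(lambda * t*) / lambda."""
    lam = kin.decay_lambda
    if lam <= 0:
        raise NonIntegrableError("non-positive decay constant has no finite integral")
    return base.a_wb_bq * math.exp(lam * base.t_star_h) / lam


def pseudo_wb_fit(base: HybridBasePoint, kin: AbdominalKinetics) -> MonoExpFit:
    """The pseudo-whole-body curve as a mono-exponential fit object.

    Its y-axis intercept A0 = A_WB(t*) * exp(lambda * t*) feeds the
    reference-vs-hybrid TAC-parameter comparison.
    """
    lam = kin.decay_lambda
    return MonoExpFit(
        amplitude_A0=base.a_wb_bq * math.exp(lam * base.t_star_h),
        decay_lambda=lam,
    )


def hybrid_bm_dose(
    patient: PatientContext,
    phantom: PhantomReference,
    sources: SourceActivitySet,
    base: HybridBasePoint,
    kin: AbdominalKinetics,
    acquired_times_h: Sequence[float] = (24.0, 48.0, 72.0),
    organs_in_model: list[str] | None = None,
    negativity_mode: Literal["strict", "clamp"] = "strict",
) -> DoseReport:
    """Marrow dose report with the whole-body TIA replaced by the pseudo TIA.

    Blood and organ components are computed from the same source set as the
    reference protocol and are therefore identical; only the ROB constituent
    differs.  ``base.t_star_h`` must be one of the acquired planar times.
    """
    if not any(math.isclose(base.t_star_h, t) for t in acquired_times_h):
        raise ConfigurationError(
            f"base-point time {base.t_star_h} h is not among the acquired planar "
            f"times {tuple(acquired_times_h)}"
        )
    label = HP_LABELS.get(int(round(base.t_star_h)), f"HP{base.t_star_h:g}")
    hybrid_sources = SourceActivitySet(
        tia_wb_bqh=pseudo_wb_tia(base, kin),
        tia_blood_conc_bqh_per_ml=sources.tia_blood_conc_bqh_per_ml,
        tia_organ_bqh=dict(sources.tia_organ_bqh),
    )
    return compute_dose_report(
        patient,
        phantom,
        hybrid_sources,
        protocol=label,
        organs_in_model=organs_in_model,
        negativity_mode=negativity_mode,
    )
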