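"""Virtual patients with the kinetic structure the dosimetry protocols assume.

A virtual patient is defined by closed-form ground-truth time-activity
curves:

* whole body: mono-exponential effective washout from the injected activity,
* abdominal SPECT field of view: mono-exponential with its own (typically
  longer) effective half-life — the mismatch the hybrid protocol is exposed
  to,
* accumulating organs: mono-exponential fractions of the injected activity,
* blood concentration: bi-exponential (fast distribution + slow washout),

so every time-integrated activity, and with a phantom every dose component,
is known analytically.  Measurements are exact curve evaluations in
noiseless mode or carry multiplicative log-normal noise (quantification
noise dominates count noise at therapy activities); a planar projection
fixture with scatter and slab attenuation exercises the image chain, with
optional Poisson counts.

All randomness flows through a single integer seed; a fixed seed reproduces
every output bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dosimetry import (
    DoseReport,
    PatientContext,
    PhantomReference,
    SourceActivitySet,
    compute_dose_report,
)
from .errors import SpecError
from .hybrid import AbdominalKinetics, HybridBasePoint, hybrid_bm_dose
from .imaging import LU177_WINDOWS, MuProjectionMap, PlanarStudy
from .tac import LN2, ActivitySample

__all__ = [
    "VirtualPatientSpec",
    "VirtualPatientTruth",
    "Measurements",
    "OCTREOTATE_LIKE",
    "PSMA_LIKE",
    "preset",
    "generate_virtual_patient",
    "sample_measurements",
    "generate_phantom_projections",
    "BLOOD_SCHEDULE_H",
    "IMAGING_SCHEDULE_H",
]

#: Clinical sampling design: blood draws at 30 and 80 min and 24/48/72 h,
#: planar + SPECT sessions at 24/48/72 h post-injection.
BLOOD_SCHEDULE_H = (0.5, 4.0 / 3.0, 24.0, 48.0, 72.0)
IMAGING_SCHEDULE_H = (24.0, 48.0, 72.0)


@dataclass(frozen=True)
class VirtualPatientSpec:
    """Generative description of one virtual patient.

    Fractions are of the injected activity at t = 0.  Organ half-lives
    default to the abdominal half-life (organs dominate the field of view).
    The tumour load rides inside the whole-body and field-of-view curves;
    ``tumour_fraction`` with ``tumour_in_fov_fraction`` only shapes the
    abdominal amplitude.
    """

    patient_id: str = "V1"
    therapy: str = "octreotate"
    sex: str = "male"
    m_wb_kg: float = 70.0
    hct: float = 0.40
    injected_activity_bq: float = 7.4e9
    wb_half_life_h: float = 43.0
    abdominal_half_life_h: float = 61.0
    organ_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"kidneys": 0.03, "liver": 0.06, "spleen": 0.01}
    )
    organ_half_lives_h: Mapping[str, float] = field(default_factory=dict)
    m_organ_kg: Mapping[str, float] = field(
        default_factory=lambda: {"kidneys": 0.30, "liver": 1.8, "spleen": 0.18}
    )
    blood_fast_half_life_h: float = 1.5
    blood_slow_half_life_h: float = 25.0
    blood_fast_fraction: float = 0.8
    blood_volume_ml: float = 5000.0
    tumour_fraction: float = 0.10
    tumour_in_fov_fraction: float = 0.7
    abdominal_organ_background_fraction: float = 0.15
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.wb_half_life_h, self.abdominal_half_life_h) <= 0:
            raise SpecError("half-lives must be positive")
        if min(self.blood_fast_half_life_h, self.blood_slow_half_life_h) <= 0:
            raise SpecError("blood half-lives must be positive")
        fr = list(self.organ_fractions.values()) + [
            self.tumour_fraction,
            self.tumour_in_fov_fraction,
            self.blood_fast_fraction,
        ]
        if any(not 0 <= f <= 1 for f in fr):
            raise SpecError("fractions must lie in [0, 1]")
        if sum(self.organ_fractions.values()) + self.tumour_fraction >= 1:
            raise SpecError("organ + tumour fractions must sum below 1")
        if not 0 < self.hct < 1:
            raise SpecError("haematocrit must lie in (0, 1)")

    def organ_half_life(self, organ: str) -> float:
        return self.organ_half_lives_h.get(organ, self.abdominal_half_life_h)


#: Paper-like presets: NET-type therapy with longer half-lives and moderate
#: tumour load; prostate-type therapy with faster blood clearance and high load.
OCTREOTATE_LIKE = VirtualPatientSpec(
    therapy="octreotate",
    wb_half_life_h=43.0,
    abdominal_half_life_h=61.0,
    blood_slow_half_life_h=25.0,
    tumour_fraction=0.10,
    injected_activity_bq=7.4e9,
    hct=0.40,
)
PSMA_LIKE = VirtualPatientSpec(
    therapy="psma617",
    wb_half_life_h=31.0,
    abdominal_half_life_h=42.0,
    blood_slow_half_life_h=14.0,
    tumour_fraction=0.25,
    injected_activity_bq=3.7e9,
    hct=0.37,
    organ_fractions={"kidneys": 0.03},
    m_organ_kg={"kidneys": 0.30},
)


def preset(name: str, **overrides) -> VirtualPatientSpec:
    """Named preset spec, with any field overridable."""
    base = {"octreotate-like": OCTREOTATE_LIKE, "psma-like": PSMA_LIKE}.get(name)
    if base is None:
        raise SpecError(f"unknown preset '{name}'")
    return replace(base, **overrides)


@dataclass(frozen=True)
class VirtualPatientTruth:
    """Analytic ground truth for one virtual patient under one phantom."""

    spec: VirtualPatientSpec
    patient: PatientContext
    sources: SourceActivitySet
    rp_report: DoseReport
    hp_reports: Mapping[str, DoseReport]
    abdominal_kinetics: AbdominalKinetics

    def wb_activity(self, t_h) -> np.ndarray:
        lam = LN2 / self.spec.wb_half_life_h
        return self.spec.injected_activity_bq * np.exp(-lam * np.asarray(t_h, float))

    def abdominal_activity(self, t_h) -> np.ndarray:
        lam = LN2 / self.spec.abdominal_half_life_h
        return _abdominal_amplitude(self.spec) * np.exp(-lam * np.asarray(t_h, float))

    def organ_activity(self, organ: str, t_h) -> np.ndarray:
        lam = LN2 / self.spec.organ_half_life(organ)
        a0 = self.spec.organ_fractions[organ] * self.spec.injected_activity_bq
        return a0 * np.exp(-lam * np.asarray(t_h, float))

    def blood_concentration(self, t_h) -> np.ndarray:
        c_fast, c_slow, lam_fast, lam_slow = _blood_params(self.spec)
        t = np.asarray(t_h, float)
        return c_fast * np.exp(-lam_fast * t) + c_slow * np.exp(-lam_slow * t)


def _blood_params(spec: VirtualPatientSpec) -> tuple[float, float, float, float]:
    c0 = spec.injected_activity_bq / spec.blood_volume_ml
    return (
        spec.blood_fast_fraction * c0,
        (1.0 - spec.blood_fast_fraction) * c0,
        LN2 / spec.blood_fast_half_life_h,
        LN2 / spec.blood_slow_half_life_h,
    )


def _abdominal_amplitude(spec: VirtualPatientSpec) -> float:
    """Initial activity inside the SPECT field of view: organs, the in-FOV
    share of the tumour load, and an unspecific abdominal background."""
    frac = (
        sum(spec.organ_fractions.values())
        + spec.tumour_fraction * spec.tumour_in_fov_fraction
        + spec.abdominal_organ_background_fraction
    )
    return frac * spec.injected_activity_bq


def generate_virtual_patient(
    spec: VirtualPatientSpec, phantom: PhantomReference
) -> VirtualPatientTruth:
    """Analytic truth bundle: TACs, TIAs and dose reports, no sampling.

    The reference-protocol truth uses the exact whole-body TIA; each hybrid
    truth anchors the abdominal decay constant at the exact on-curve
    whole-body activity at 24/48/72 h.
    """
    patient = PatientContext(
        patient_id=spec.patient_id,
        sex=spec.sex,  # type: ignore[arg-type]
        therapy=spec.therapy,  # type: ignore[arg-type]
        injected_activity_bq=spec.injected_activity_bq,
        m_wb_kg=spec.m_wb_kg,
        hct=spec.hct,
        m_organ_kg=dict(spec.m_organ_kg),
    )
    lam_wb = LN2 / spec.wb_half_life_h
    tia_wb = spec.injected_activity_bq / lam_wb
    c_fast, c_slow, lam_fast, lam_slow = _blood_params(spec)
    tia_blood = c_fast / lam_fast + c_slow / lam_slow
    tia_organs = {
        organ: frac * spec.injected_activity_bq / (LN2 / spec.organ_half_life(organ))
        for organ, frac in spec.organ_fractions.items()
    }
    sources = SourceActivitySet(
        tia_wb_bqh=tia_wb,
        tia_blood_conc_bqh_per_ml=tia_blood,
        tia_organ_bqh=tia_organs,
    )
    rp = compute_dose_report(patient, phantom, sources, protocol="RP")
    kin = AbdominalKinetics(decay_lambda=LN2 / spec.abdominal_half_life_h)
    hp_reports = {}
    for t_star in IMAGING_SCHEDULE_H:
        base = HybridBasePoint(
            t_star_h=t_star,
            a_wb_bq=spec.injected_activity_bq * math.exp(-lam_wb * t_star),
        )
        report = hybrid_bm_dose(patient, phantom, sources, base, kin)
        hp_reports[report.protocol] = report
    return VirtualPatientTruth(
        spec=spec,
        patient=patient,
        sources=sources,
        rp_report=rp,
        hp_reports=hp_reports,
        abdominal_kinetics=kin,
    )


@dataclass(frozen=True)
class Measurements:
    """Sampled (noiseless or noisy) measurements for one virtual patient."""

    patient_id: str
    blood_samples: tuple[ActivitySample, ...]
    planar_wb_bq: tuple[ActivitySample, ...]
    spect_fov_bq: tuple[ActivitySample, ...]
    spect_organ_bq: Mapping[str, tuple[ActivitySample, ...]]


def sample_measurements(
    truth: VirtualPatientTruth,
    blood_times_h: Sequence[float] = BLOOD_SCHEDULE_H,
    imaging_times_h: Sequence[float] = IMAGING_SCHEDULE_H,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> Measurements:
    """Evaluate the truth curves on the clinical schedule.

    ``noise_sigma`` overrides the spec's sigma; 0 gives exact curve values.
    Noise is multiplicative log-normal, exp(sigma * z) with z ~ N(0, 1),
    drawn from a generator seeded with ``seed`` (default: the spec's seed).
    """
    spec = truth.spec
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    def noisy(values: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return values
        return values * np.exp(sigma * rng.standard_normal(values.shape))

    blood = noisy(truth.blood_concentration(blood_times_h))
    planar = noisy(truth.wb_activity(imaging_times_h))
    fov = noisy(truth.abdominal_activity(imaging_times_h))
    organs = {
        organ: noisy(truth.organ_activity(organ, imaging_times_h))
        for organ in spec.organ_fractions
    }
    return Measurements(
        patient_id=spec.patient_id,
        blood_samples=tuple(
            ActivitySample(t, float(v), "concentration")
            for t, v in zip(blood_times_h, blood)
        ),
        planar_wb_bq=tuple(
            ActivitySample(t, float(v)) for t, v in zip(imaging_times_h, planar)
        ),
        spect_fov_bq=tuple(
            ActivitySample(t, float(v)) for t, v in zip(imaging_times_h, fov)
        ),
        spect_organ_bq={
            organ: tuple(
                ActivitySample(t, float(v)) for t, v in zip(imaging_times_h, vals)
            )
            for organ, vals in organs.items()
        },
    )


def generate_phantom_projections(
    shape: tuple[int, int] = (64, 32),
    total_activity_bq: float = 1.0e8,
    mu_per_mm: float = 0.0095,
    thickness_mm: float = 200.0,
    scatter_fraction: float = 0.3,
    sensitivity_cps_per_bq: float = 1.0e-4,
    duration_s: float = 1200.0,
    pixel_mm: float = 2.4,
    time_h: float = 24.0,
    poisson: bool = False,
    seed: int = 0,
) -> tuple[PlanarStudy, MuProjectionMap, float]:
    """Anterior/posterior projection fixture with scatter and slab attenuation.

    The activity lies in a smooth 2D distribution at mid-depth of a uniform
    water-equivalent slab, so both views see the transmission factor
    exp(-mu * thickness / 2).  Scatter adds ``scatter_fraction`` of the
    primary counts to the photopeak and fills the flanking windows so that
    the triple-energy-window estimate reproduces it (trapezoidal geometry).
    Returns the study, the true (unblurred) optical-depth map, and the true
    total activity.

    In noiseless mode (``poisson=False``) the TEW -> conjugate-view ->
    SPECT-anchored calibration chain recovers the total activity exactly.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    # two smooth blobs, deterministic positions jittered by the seed
    cy1, cx1 = rows * 0.35 + rng.uniform(-2, 2), cols * 0.5 + rng.uniform(-2, 2)
    cy2, cx2 = rows * 0.7 + rng.uniform(-2, 2), cols * 0.4 + rng.uniform(-2, 2)
    blob = np.exp(-(((yy - cy1) / (rows * 0.12)) ** 2 + ((xx - cx1) / (cols * 0.2)) ** 2))
    blob += 0.6 * np.exp(
        -(((yy - cy2) / (rows * 0.1)) ** 2 + ((xx - cx2) / (cols * 0.15)) ** 2)
    )
    activity = blob / blob.sum() * total_activity_bq

    depth = np.full(shape, mu_per_mm * thickness_mm)
    transmission_half = np.exp(-depth / 2.0)
    primary = activity * sensitivity_cps_per_bq * duration_s * transmission_half
    scatter_in_peak = scatter_fraction * primary

    w_peak, w_lower, w_upper = LU177_WINDOWS.absolute_widths()
    lower = scatter_in_peak * w_lower / w_peak
    upper = scatter_in_peak * w_upper / w_peak
    peak = primary + scatter_in_peak

    def counts(img: np.ndarray) -> np.ndarray:
        return rng.poisson(img).astype(float) if poisson else img

    study = PlanarStudy(
        ant_peak=counts(peak),
        post_peak=counts(peak.copy()),
        ant_lower=counts(lower),
        post_lower=counts(lower.copy()),
        ant_upper=counts(upper),
        post_upper=counts(upper.copy()),
        duration_s=duration_s,
        pixel_mm=pixel_mm,
        time_h=time_h,
    )
    mu_map = MuProjectionMap(
        optical_depth=depth, provenance=np.zeros(shape, dtype=np.int8)
    )
    return study, mu_map, total_activity_bq
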