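"""Organ-level bone-marrow dosimetry (MIRD formalism with mass-scaled S values).

The total red-marrow absorbed dose is assembled from three constituents:

* **blood self-dose** — the blood method: the marrow extracellular fluid is
  assumed in equilibrium with the blood (plasma), so the marrow TIA is the
  blood concentration TIA times the red-marrow-to-blood activity
  concentration ratio (RMBLR) times the patient marrow mass,

      D_blood = [A~_blood] * RMBLR * m_BM,pat * S(BM<-BM) * (m_BM,ph/m_BM,pat)^a

  with RMBLR = RMECFF / (1 - HCT) for PSMA-617 (no specific marrow/cell
  binding; only the extracellular fluid fraction of plasma activity) and
  RMBLR = 1 for Octreotate;

* **organ cross-dose** — per accumulating organ,

      D_organ = A~_organ * S(BM<-organ) * (m_org,ph/m_org,pat) * (m_BM,ph/m_BM,pat);

* **remainder-of-body (ROB) cross-dose** — the whole-body TIA minus the blood
  term and the explicit organs (all tumours stay inside the ROB), converted
  with the Hindorf-style three-term S-value bracket whose whole-body, marrow
  and organ factors are mass-scaled with the non-linear exponents a, b, c.

All S values are reference-phantom values scaled to the patient anatomy.
Masses are kept in kilograms on the data classes and converted to grams
inside the equations, where 1 ml of blood is taken as 1 g so that
(Bq h/ml) x g is Bq h.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .errors import (
    AssemblyError,
    ConfigurationError,
    DomainError,
    InconsistencyError,
    NonPhysicalSValueError,
)

__all__ = [
    "RMECFF_DEFAULT",
    "TRAINO_EXPONENTS",
    "PhantomReference",
    "PatientContext",
    "SourceActivitySet",
    "DoseReport",
    "rmblr",
    "scale_svalue",
    "blood_dose",
    "organ_dose",
    "rob_tia",
    "rob_dose",
    "total_bm_dose",
    "compute_dose_report",
]

#: Red-marrow extracellular fluid fraction.
RMECFF_DEFAULT = 0.19

#: Non-linear mass-scaling exponents (Traino-style), by phantom sex:
#: a scales the marrow self-S value, b the whole-body mass ratio and c the
#: marrow mass ratio of the ROB bracket.
TRAINO_EXPONENTS = {
    "male": {"a": 1.001, "b": 0.896, "c": 0.963},
    "female": {"a": 0.992, "b": 0.894, "c": 0.970},
}

_G_PER_KG = 1000.0


@dataclass(frozen=True)
class PhantomReference:
    """Reference anthropomorphic phantom: masses, S values and exponents.

    Masses in kg; S values in Gy/(Bq h).  ``s_bm_organ`` and ``m_organ`` are
    keyed by organ name (e.g. kidneys, liver, spleen).
    """

    sex: Literal["male", "female"]
    m_wb_kg: float
    m_bm_kg: float
    m_organ_kg: Mapping[str, float]
    s_bm_bm: float
    s_bm_wb: float
    s_bm_organ: Mapping[str, float]
    a: float = None  # type: ignore[assignment]
    b: float = None  # type: ignore[assignment]
    c: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.sex not in TRAINO_EXPONENTS:
            raise ConfigurationError(f"unknown phantom sex '{self.sex}'")
        defaults = TRAINO_EXPONENTS[self.sex]
        for name in ("a", "b", "c"):
            val = getattr(self, name)
            if val is None:
                object.__setattr__(self, name, defaults[name])
            elif not 0.5 < val < 1.5:
                raise ConfigurationError(f"exponent {name}={val} outside (0.5, 1.5)")
        if min(self.m_wb_kg, self.m_bm_kg, self.s_bm_bm, self.s_bm_wb) <= 0:
            raise ConfigurationError("phantom masses and S values must be positive")
        for organ in self.s_bm_organ:
            if organ not in self.m_organ_kg:
                raise ConfigurationError(f"phantom S value for '{organ}' lacks a mass")

    def organ_svalue(self, organ: str) -> float:
        try:
            return self.s_bm_organ[organ]
        except KeyError:
            raise ConfigurationError(f"no phantom S value for organ '{organ}'") from None

    def organ_mass_kg(self, organ: str) -> float:
        try:
            return self.m_organ_kg[organ]
        except KeyError:
            raise ConfigurationError(f"no phantom mass for organ '{organ}'") from None

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomReference":
        return cls(
            sex=d["sex"],
            m_wb_kg=float(d["m_wb_kg"]),
            m_bm_kg=float(d["m_bm_kg"]),
            m_organ_kg={k: float(v) for k, v in d.get("m_organ_kg", {}).items()},
            s_bm_bm=float(d["s_bm_bm"]),
            s_bm_wb=float(d["s_bm_wb"]),
            s_bm_organ={k: float(v) for k, v in d.get("s_bm_organ", {}).items()},
            a=d.get("a"),
            b=d.get("b"),
            c=d.get("c"),
        )


@dataclass
class PatientContext:
    """Patient anatomy and therapy context.

    Marrow mass defaults to linear body-mass scaling of the phantom marrow
    mass, m_BM,pat = m_BM,ph * (m_WB,pat / m_WB,ph); the remainder-of-body
    mass to whole body minus marrow minus explicit organs.  Both are
    overridable.
    """

    patient_id: str
    sex: Literal["male", "female"]
    therapy: Literal["octreotate", "psma617"]
    injected_activity_bq: float
    m_wb_kg: float
    hct: float
    m_organ_kg: dict[str, float] = field(default_factory=dict)
    m_bm_kg: float | None = None
    m_rob_kg: float | None = None
    rmecff: float = RMECFF_DEFAULT

    def __post_init__(self):
        if not 0 < self.hct < 1:
            raise DomainError(f"haematocrit must be in (0, 1), got {self.hct}")
        if self.m_wb_kg <= 0 or self.injected_activity_bq <= 0:
            raise DomainError("body mass and injected activity must be positive")
        if self.therapy not in ("octreotate", "psma617"):
            raise ConfigurationError(f"unknown therapy '{self.therapy}'")

    def bm_mass_kg(self, phantom: PhantomReference) -> float:
        if self.m_bm_kg is not None:
            return self.m_bm_kg
        return phantom.m_bm_kg * self.m_wb_kg / phantom.m_wb_kg

    def rob_mass_kg(self, phantom: PhantomReference) -> float:
        if self.m_rob_kg is not None:
            return self.m_rob_kg
        m_rob = self.m_wb_kg - self.bm_mass_kg(phantom) - sum(self.m_organ_kg.values())
        if m_rob <= 0:
            raise ConfigurationError(
                f"derived ROB mass non-positive for patient {self.patient_id}"
            )
        return m_rob

    def organ_mass_kg(self, organ: str) -> float:
        try:
            return self.m_organ_kg[organ]
        except KeyError:
            raise ConfigurationError(
                f"patient {self.patient_id} has no mass for organ '{organ}'"
            ) from None


@dataclass
class SourceActivitySet:
    """Time-integrated activities feeding the dose equations.

    ``tia_wb_bqh`` in Bq h, ``tia_blood_conc_bqh_per_ml`` in Bq h/ml,
    ``tia_organ_bqh`` per organ in Bq h.  The ROB TIA is derived, see
    :func:`rob_tia`.
    """

    tia_wb_bqh: float
    tia_blood_conc_bqh_per_ml: float
    tia_organ_bqh: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.tia_wb_bqh < 0 or self.tia_blood_conc_bqh_per_ml < 0:
            raise DomainError("time-integrated activities must be non-negative")
        if any(v < 0 for v in self.tia_organ_bqh.values()):
            raise DomainError("organ time-integrated activities must be non-negative")


@dataclass
class DoseReport:
    """Absorbed-dose components for one patient under one protocol."""

    patient_id: str
    protocol: str
    d_blood_gy: float
    d_organ_gy: dict[str, float]
    d_rob_gy: float
    injected_activity_bq: float

    def __post_init__(self):
        if self.injected_activity_bq <= 0:
            raise AssemblyError("injected activity must be positive")

    @property
    def d_organs_gy(self) -> float:
        return sum(self.d_organ_gy.values())

    @property
    def d_total_gy(self) -> float:
        return self.d_blood_gy + self.d_organs_gy + self.d_rob_gy

    @property
    def d_total_mgy_per_gbq(self) -> float:
        return self.d_total_gy * 1e3 / (self.injected_activity_bq / 1e9)

    @property
    def d_rob_mgy_per_gbq(self) -> float:
        return self.d_rob_gy * 1e3 / (self.injected_activity_bq / 1e9)

    def contributions_percent(self) -> dict[str, float]:
        """Percentage contribution of each constituent to the total dose."""
        total = self.d_total_gy
        if total <= 0:
            raise AssemblyError("total dose must be positive for contributions")
        pc = {
            "blood": 100.0 * self.d_blood_gy / total,
            "organs": 100.0 * self.d_organs_gy / total,
            "rob": 100.0 * self.d_rob_gy / total,
        }
        assert abs(sum(pc.values()) - 100.0) < 1e-9
        return pc

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "protocol": self.protocol,
            "d_blood_gy": self.d_blood_gy,
            "d_organ_gy": dict(self.d_organ_gy),
            "d_rob_gy": self.d_rob_gy,
            "d_total_gy": self.d_total_gy,
            "d_total_mgy_per_gbq": self.d_total_mgy_per_gbq,
            "d_rob_mgy_per_gbq": self.d_rob_mgy_per_gbq,
            "contributions_percent": self.contributions_percent(),
            "injected_activity_bq": self.injected_activity_bq,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def rmblr(therapy: str, hct: float, rmecff: float = RMECFF_DEFAULT) -> float:
    """Red-marrow-to-blood activity concentration ratio.

    PSMA-617: RMECFF / (1 - HCT) — only the extracellular-fluid share of the
    plasma activity reaches the marrow.  Octreotate: 1 exactly.
    """
    if not 0 < hct < 1:
        raise DomainError(f"haematocrit must be in (0, 1), got {hct}")
    if therapy == "octreotate":
        return 1.0
    if therapy == "psma617":
        return rmecff / (1.0 - hct)
    raise ConfigurationError(f"unknown therapy '{therapy}'")


def scale_svalue(
    kind: Literal["bm_self", "wb_to_bm", "organ_to_bm", "rob_terms"],
    phantom: PhantomReference,
    patient: PatientContext,
    organ: str | None = None,
):
    """Mass-scaled S value (or ROB term bundle) for the patient anatomy.

    * ``bm_self``:     S(BM<-BM) * (m_BM,ph / m_BM,pat)^a
    * ``organ_to_bm``: S(BM<-organ) * (m_org,ph/m_org,pat) * (m_BM,ph/m_BM,pat)
    * ``wb_to_bm``:    S(BM<-WB) * (m_WB,ph/m_WB,pat)^b * (m_BM,ph/m_BM,pat)^c
    * ``rob_terms``:   the three bracket terms of the ROB conversion, as a
      dict {"wb": ..., "bm": ..., "organs": {organ: ...}}; their combination
      (wb - bm - sum(organs)) is the effective ROB S value.
    """
    m_bm_pat = patient.bm_mass_kg(phantom)
    bm_ratio = phantom.m_bm_kg / m_bm_pat
    if kind == "bm_self":
        return phantom.s_bm_bm * bm_ratio**phantom.a
    if kind == "organ_to_bm":
        if organ is None:
            raise ConfigurationError("organ_to_bm scaling requires an organ name")
        return (
            phantom.organ_svalue(organ)
            * (phantom.organ_mass_kg(organ) / patient.organ_mass_kg(organ))
            * bm_ratio
        )
    if kind == "wb_to_bm":
        return (
            phantom.s_bm_wb
            * (phantom.m_wb_kg / patient.m_wb_kg) ** phantom.b
            * bm_ratio**phantom.c
        )
    if kind == "rob_terms":
        m_rob_pat = patient.rob_mass_kg(phantom)
        wb_term = scale_svalue("wb_to_bm", phantom, patient)
        bm_term = phantom.s_bm_bm * ((phantom.m_bm_kg / m_rob_pat) * bm_ratio) ** phantom.a
        organ_terms = {
            org: phantom.s_bm_organ[org] * (phantom.organ_mass_kg(org) / m_rob_pat) * bm_ratio
            for org in patient.m_organ_kg
            if org in phantom.s_bm_organ
        }
        return {"wb": wb_term, "bm": bm_term, "organs": organ_terms}
    raise ConfigurationError(f"unknown S-value scaling kind '{kind}'")


def _blood_tia_bqh(
    tia_blood_conc_bqh_per_ml: float, patient: PatientContext, phantom: PhantomReference
) -> float:
    """Marrow-resident blood TIA: [A~_blood] * RMBLR * m_BM,pat (grams, 1 ml = 1 g)."""
    ratio = rmblr(patient.therapy, patient.hct, patient.rmecff)
    return tia_blood_conc_bqh_per_ml * ratio * patient.bm_mass_kg(phantom) * _G_PER_KG


def blood_dose(
    tia_blood_conc_bqh_per_ml: float,
    patient: PatientContext,
    phantom: PhantomReference,
) -> float:
    """Marrow self-dose (Gy) from the blood concentration TIA (blood method)."""
    if tia_blood_conc_bqh_per_ml < 0:
        raise DomainError("blood TIA must be non-negative")
    tia_bqh = _blood_tia_bqh(tia_blood_conc_bqh_per_ml, patient, phantom)
    return tia_bqh * scale_svalue("bm_self", phantom, patient)


def organ_dose(
    tia_organ_bqh: float,
    organ: str,
    patient: PatientContext,
    phantom: PhantomReference,
) -> float:
    """Marrow cross-dose (Gy) from one accumulating organ."""
    if tia_organ_bqh < 0:
        raise DomainError("organ TIA must be non-negative")
    return tia_organ_bqh * scale_svalue("organ_to_bm", phantom, patient, organ=organ)


def rob_tia(
    tia_wb_bqh: float,
    tia_blood_conc_bqh_per_ml: float,
    patient: PatientContext,
    phantom: PhantomReference,
    tia_organ_bqh: Mapping[str, float],
    mode: Literal["strict", "clamp"] = "strict",
) -> float:
    """Remainder-of-body TIA: whole body minus blood term minus organs (Bq h).

    A negative result signals a quantification fault (e.g. a planar/SPECT
    calibration mismatch); ``strict`` raises, ``clamp`` floors at zero.
    """
    if tia_wb_bqh < 0 or tia_blood_conc_bqh_per_ml < 0:
        raise DomainError("time-integrated activities must be non-negative")
    blood_term = _blood_tia_bqh(tia_blood_conc_bqh_per_ml, patient, phantom)
    organs = sum(tia_organ_bqh.values())
    result = tia_wb_bqh - blood_term - organs
    if result < 0:
        if mode == "clamp":
            return 0.0
        raise InconsistencyError(
            "negative remainder-of-body TIA: "
            f"WB {tia_wb_bqh:.4g} - blood {blood_term:.4g} - organs {organs:.4g} "
            f"= {result:.4g} Bq h (patient {patient.patient_id})"
        )
    return result


def rob_dose(
    tia_rob_bqh: float,
    patient: PatientContext,
    phantom: PhantomReference,
    organs_in_model: list[str] | None = None,
) -> float:
    """Marrow cross-dose (Gy) from the remainder of body.

    The bracket subtracts from the whole-body conversion the marrow-self and
    explicit-organ shares, each mass-scaled; a non-positive bracket means
    the S-value configuration is inconsistent.
    """
    if tia_rob_bqh < 0:
        raise DomainError("ROB TIA must be non-negative")
    if organs_in_model is None:
        organs_in_model = list(patient.m_organ_kg)
    m_bm_pat = patient.bm_mass_kg(phantom)
    m_rob_pat = patient.rob_mass_kg(phantom)
    bm_ratio = phantom.m_bm_kg / m_bm_pat
    wb_term = (
        phantom.s_bm_wb
        * (phantom.m_wb_kg / patient.m_wb_kg) ** phantom.b
        * bm_ratio**phantom.c
    )
    bm_term = phantom.s_bm_bm * ((phantom.m_bm_kg / m_rob_pat) * bm_ratio) ** phantom.a
    organ_sum = 0.0
    for organ in organs_in_model:
        organ_sum += (
            phantom.organ_svalue(organ)
            * (phantom.organ_mass_kg(organ) / m_rob_pat)
            * bm_ratio
        )
    bracket = wb_term - bm_term - organ_sum
    if bracket <= 0:
        raise NonPhysicalSValueError(
            "non-positive ROB S-value bracket: "
            f"WB term {wb_term:.4g} - BM term {bm_term:.4g} - organ terms {organ_sum:.4g}"
        )
    return tia_rob_bqh * bracket


def total_bm_dose(
    patient_id: str,
    protocol: str,
    d_blood_gy: float,
    d_organ_gy: Mapping[str, float],
    d_rob_gy: float,
    injected_activity_bq: float,
) -> DoseReport:
    """Assemble the constituent doses into a report (Gy and mGy/GBq)."""
    for name, val in (("blood", d_blood_gy), ("rob", d_rob_gy)):
        if val is None or val < 0:
            raise AssemblyError(f"missing or negative {name} dose component")
    return DoseReport(
        patient_id=patient_id,
        protocol=protocol,
        d_blood_gy=float(d_blood_gy),
        d_organ_gy={k: float(v) for k, v in d_organ_gy.items()},
        d_rob_gy=float(d_rob_gy),
        injected_activity_bq=float(injected_activity_bq),
    )


def compute_dose_report(
    patient: PatientContext,
    phantom: PhantomReference,
    sources: SourceActivitySet,
    protocol: str = "RP",
    organs_in_model: list[str] | None = None,
    negativity_mode: Literal["strict", "clamp"] = "strict",
) -> DoseReport:
    """Full marrow dose for one patient from its time-integrated activities."""
    if organs_in_model is None:
        organs_in_model = list(sources.tia_organ_bqh)
    d_blood = blood_dose(sources.tia_blood_conc_bqh_per_ml, patient, phantom)
    d_organs = {
        organ: organ_dose(sources.tia_organ_bqh[organ], organ, patient, phantom)
        for organ in organs_in_model
    }
    tia_rob = rob_tia(
        sources.tia_wb_bqh,
        sources.tia_blood_conc_bqh_per_ml,
        patient,
        phantom,
        {o: sources.tia_organ_bqh[o] for o in organs_in_model},
        mode=negativity_mode,
    )
    d_rob = rob_dose(tia_rob, patient, phantom, organs_in_model)
    return total_bm_dose(
        patient.patient_id,
        protocol,
        d_blood,
        d_organs,
        d_rob,
        patient.injected_activity_bq,
    )
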