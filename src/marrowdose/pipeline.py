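"""End-to-end protocol orchestration.

Runs the reference protocol (three planar + three SPECT sessions + five
blood draws) and the hybrid protocols (single planar anchor + sequential
SPECT) over a cohort, isolates per-patient failures, keeps a machine-
readable audit of every intermediate (fits, TIAs), and assembles the
protocol comparison.

Measurement series are exchanged as tidy CSV with columns
``patient_id, source, time_h, value, unit`` where ``source`` is one of
``planar_wb``, ``spect_fov``, ``blood`` or ``organ:<name>``; dose reports
are serialised to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .compare import (
    cohort_summary,
    pearson_correlation,
    percentage_deviation,
    tac_parameter_ratios,
)
from .config import DEFAULT_ORGAN_MODEL
from .dosimetry import (
    DoseReport,
    PatientContext,
    PhantomReference,
    SourceActivitySet,
    compute_dose_report,
)
from .errors import ConfigurationError, InsufficientDataError, MarrowDoseError
from .hybrid import (
    HP_LABELS,
    HybridBasePoint,
    abdominal_decay_constant,
    hybrid_bm_dose,
    pseudo_wb_fit,
)
from .tac import ActivitySample, fit_biexp, fit_monoexp, integrate_to_infinity

__all__ = [
    "PatientDataset",
    "RunConfig",
    "CohortResult",
    "run_reference",
    "run_hybrid",
    "measurements_to_frame",
    "frame_to_datasets",
]

PROTOCOLS = ("reference", "HP24", "HP48", "HP72", "all")


@dataclass
class PatientDataset:
    """One patient's context plus calibrated measurement series."""

    patient: PatientContext
    blood_samples: Sequence[ActivitySample]
    planar_wb_bq: Sequence[ActivitySample]
    spect_fov_bq: Sequence[ActivitySample]
    spect_organ_bq: Mapping[str, Sequence[ActivitySample]] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Cohort-run configuration.

    ``organ_model`` defaults per therapy (kidneys for both; liver and spleen
    added for octreotate).  ``negativity_mode`` selects strict raising vs
    clamping of a negative remainder-of-body TIA.
    """

    protocol: str = "reference"
    organ_model: list[str] | None = None
    negativity_mode: Literal["strict", "clamp"] = "strict"
    min_planar_points: int = 3
    out_dir: Path | None = None

    def __post_init__(self):
        if self.protocol not in PROTOCOLS:
            raise ConfigurationError(
                f"protocol must be one of {PROTOCOLS}, got '{self.protocol}'"
            )

    def organs_for(self, therapy: str) -> list[str]:
        if self.organ_model is not None:
            return list(self.organ_model)
        return list(DEFAULT_ORGAN_MODEL[therapy])


@dataclass
class CohortResult:
    """Reports per patient/protocol, failures, audit trail and comparison."""

    reports: dict[str, dict[str, DoseReport]]  # patient_id -> protocol -> report
    failures: dict[str, str]
    audit: dict[str, dict]
    comparison: pd.DataFrame | None = None
    cohort_summary: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        """Flat per-patient/protocol dose table (mGy/GBq)."""
        rows = []
        for pid, by_proto in self.reports.items():
            for proto, rep in by_proto.items():
                rows.append(
                    {
                        "patient_id": pid,
                        "protocol": proto,
                        "d_total_mgy_per_gbq": rep.d_total_mgy_per_gbq,
                        "d_rob_mgy_per_gbq": rep.d_rob_mgy_per_gbq,
                        **{
                            f"pc_{k}_percent": v
                            for k, v in rep.contributions_percent().items()
                        },
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(out_dir / "doses.csv", index=False)
        with open(out_dir / "audit.json", "w") as fh:
            json.dump(self.audit, fh, indent=2)
        if self.failures:
            with open(out_dir / "failures.json", "w") as fh:
                json.dump(self.failures, fh, indent=2)
        if self.comparison is not None:
            self.comparison.to_csv(out_dir / "comparison.csv", index=False)
        if self.cohort_summary is not None:
            self.cohort_summary.to_csv(out_dir / "cohort_summary.csv", index=False)


def _reference_sources(
    ds: PatientDataset, config: RunConfig, audit: dict
) -> SourceActivitySet:
    organs = config.organs_for(ds.patient.therapy)
    if len(ds.planar_wb_bq) < config.min_planar_points:
        raise InsufficientDataError(
            f"reference protocol needs >= {config.min_planar_points} planar points"
        )
    wb_fit = fit_monoexp(ds.planar_wb_bq, min_points=config.min_planar_points)
    blood_fit = fit_biexp(ds.blood_samples)
    tia_organ = {}
    for organ in organs:
        if organ not in ds.spect_organ_bq:
            raise InsufficientDataError(f"missing SPECT series for organ '{organ}'")
        o_fit = fit_monoexp(ds.spect_organ_bq[organ])
        tia_organ[organ] = integrate_to_infinity(o_fit)
        audit[f"organ_fit:{organ}"] = o_fit.to_dict()
    audit["wb_fit"] = wb_fit.to_dict()
    audit["blood_fit"] = blood_fit.to_dict()
    sources = SourceActivitySet(
        tia_wb_bqh=integrate_to_infinity(wb_fit),
        tia_blood_conc_bqh_per_ml=integrate_to_infinity(blood_fit),
        tia_organ_bqh=tia_organ,
    )
    audit["tia"] = {
        "wb_bqh": sources.tia_wb_bqh,
        "blood_conc_bqh_per_ml": sources.tia_blood_conc_bqh_per_ml,
        "organ_bqh": dict(sources.tia_organ_bqh),
    }
    return sources


def run_reference(
    cohort: Sequence[PatientDataset],
    phantom: PhantomReference,
    config: RunConfig | None = None,
) -> CohortResult:
    """Reference protocol over a cohort; one patient's failure never aborts."""
    config = config or RunConfig(protocol="reference")
    reports: dict[str, dict[str, DoseReport]] = {}
    failures: dict[str, str] = {}
    audit: dict[str, dict] = {}
    for ds in cohort:
        pid = ds.patient.patient_id
        patient_audit: dict = {}
        try:
            sources = _reference_sources(ds, config, patient_audit)
            rep = compute_dose_report(
                ds.patient,
                phantom,
                sources,
                protocol="RP",
                organs_in_model=config.organs_for(ds.patient.therapy),
                negativity_mode=config.negativity_mode,
            )
            reports[pid] = {"RP": rep}
        except MarrowDoseError as exc:
            failures[pid] = f"{type(exc).__name__}: {exc}"
        audit[pid] = patient_audit
    return CohortResult(reports=reports, failures=failures, audit=audit)


def _requested_hp_labels(protocol: str) -> list[str]:
    if protocol == "all":
        return list(HP_LABELS.values())
    if protocol in HP_LABELS.values():
        return [protocol]
    raise ConfigurationError(f"'{protocol}' is not a hybrid protocol")


def run_hybrid(
    cohort: Sequence[PatientDataset],
    phantom: PhantomReference,
    config: RunConfig | None = None,
) -> CohortResult:
    """Hybrid protocol(s) over a cohort, plus the RP comparison when the
    sequential planar data are available.

    The base-point activity is the measured planar activity at t*, not the
    fitted value.  Per HP label, the comparison collects total and ROB dose
    deviations and the reference-to-hybrid TAC parameter ratios.
    """
    config = config or RunConfig(protocol="all")
    labels = _requested_hp_labels(config.protocol)
    reports: dict[str, dict[str, DoseReport]] = {}
    failures: dict[str, str] = {}
    audit: dict[str, dict] = {}
    rows = []
    for ds in cohort:
        pid = ds.patient.patient_id
        patient_audit: dict = {}
        try:
            organs = config.organs_for(ds.patient.therapy)
            sources = _reference_sources(ds, config, patient_audit)
            kin = abdominal_decay_constant(ds.spect_fov_bq)
            patient_audit["abdominal_fit"] = kin.source_fit.to_dict()
            by_proto: dict[str, DoseReport] = {}
            rp_available = len(ds.planar_wb_bq) >= config.min_planar_points
            rp_rep = None
            wb_fit = None
            if rp_available:
                rp_rep = compute_dose_report(
                    ds.patient,
                    phantom,
                    sources,
                    protocol="RP",
                    organs_in_model=organs,
                    negativity_mode=config.negativity_mode,
                )
                by_proto["RP"] = rp_rep
                wb_fit = fit_monoexp(ds.planar_wb_bq, min_points=config.min_planar_points)
            planar_by_time = {round(s.time): s for s in ds.planar_wb_bq}
            for label in labels:
                t_star = {v: k for k, v in HP_LABELS.items()}[label]
                if t_star not in planar_by_time:
                    raise ConfigurationError(
                        f"no planar acquisition at {t_star} h for patient {pid}"
                    )
                base = HybridBasePoint(
                    t_star_h=float(t_star), a_wb_bq=planar_by_time[t_star].value
                )
                hp_rep = hybrid_bm_dose(
                    ds.patient,
                    phantom,
                    sources,
                    base,
                    kin,
                    organs_in_model=organs,
                    negativity_mode=config.negativity_mode,
                )
                by_proto[label] = hp_rep
                if rp_rep is not None:
                    ratios = tac_parameter_ratios(wb_fit, pseudo_wb_fit(base, kin))
                    rows.append(
                        {
                            "patient_id": pid,
                            "therapy": ds.patient.therapy,
                            "protocol": label,
                            "d_total_rp_mgy_per_gbq": rp_rep.d_total_mgy_per_gbq,
                            "d_total_hp_mgy_per_gbq": hp_rep.d_total_mgy_per_gbq,
                            "d_rob_rp_mgy_per_gbq": rp_rep.d_rob_mgy_per_gbq,
                            "d_rob_hp_mgy_per_gbq": hp_rep.d_rob_mgy_per_gbq,
                            "pd_total_percent": percentage_deviation(
                                hp_rep.d_total_mgy_per_gbq, rp_rep.d_total_mgy_per_gbq
                            ),
                            "pd_rob_percent": percentage_deviation(
                                hp_rep.d_rob_mgy_per_gbq, rp_rep.d_rob_mgy_per_gbq
                            ),
                            "a0_ratio": ratios.a0_ratio,
                            "half_life_ratio": ratios.half_life_ratio,
                            "ratio_product": ratios.product,
                        }
                    )
            reports[pid] = by_proto
        except MarrowDoseError as exc:
            failures[pid] = f"{type(exc).__name__}: {exc}"
        audit[pid] = patient_audit

    comparison = pd.DataFrame(rows) if rows else None
    summary = None
    if comparison is not None and not comparison.empty:
        summary_rows = []
        for (therapy, label), grp in comparison.groupby(["therapy", "protocol"]):
            for metric in ("pd_total_percent", "pd_rob_percent", "half_life_ratio"):
                med, lo, hi = cohort_summary(grp[metric].tolist())
                summary_rows.append(
                    {
                        "therapy": therapy,
                        "protocol": label,
                        "metric": metric,
                        "median": med,
                        "min": lo,
                        "max": hi,
                    }
                )
            if len(grp) >= 3:
                try:
                    r, p = pearson_correlation(
                        grp["d_total_rp_mgy_per_gbq"], grp["d_total_hp_mgy_per_gbq"]
                    )
                except MarrowDoseError:
                    continue  # degenerate cohort (zero variance)
                summary_rows.append(
                    {
                        "therapy": therapy,
                        "protocol": label,
                        "metric": "pearson_r_total",
                        "median": r,
                        "min": p,
                        "max": p,
                    }
                )
        summary = pd.DataFrame(summary_rows)
    return CohortResult(
        reports=reports,
        failures=failures,
        audit=audit,
        comparison=comparison,
        cohort_summary=summary,
    )


# ---------------------------------------------------------------------------
# tidy-CSV measurement exchange


def measurements_to_frame(datasets: Sequence[PatientDataset]) -> pd.DataFrame:
    """Serialise measurement series to the tidy CSV layout."""
    rows = []
    for ds in datasets:
        pid = ds.patient.patient_id
        for s in ds.blood_samples:
            rows.append((pid, "blood", s.time, s.value, "Bq/ml"))
        for s in ds.planar_wb_bq:
            rows.append((pid, "planar_wb", s.time, s.value, "Bq"))
        for s in ds.spect_fov_bq:
            rows.append((pid, "spect_fov", s.time, s.value, "Bq"))
        for organ, series in ds.spect_organ_bq.items():
            for s in series:
                rows.append((pid, f"organ:{organ}", s.time, s.value, "Bq"))
    return pd.DataFrame(
        rows, columns=["patient_id", "source", "time_h", "value", "unit"]
    )


def frame_to_datasets(
    frame: pd.DataFrame, patients: Mapping[str, PatientContext]
) -> list[PatientDataset]:
    """Rebuild patient datasets from the tidy CSV layout plus contexts."""
    datasets = []
    for pid, grp in frame.groupby("patient_id"):
        if pid not in patients:
            raise ConfigurationError(f"no patient context for '{pid}'")

        def series(sel, kind="activity"):
            sel = sel.sort_values("time_h")
            return [
                ActivitySample(float(t), float(v), kind)
                for t, v in zip(sel["time_h"], sel["value"])
            ]

        organs = {}
        for src in grp["source"].unique():
            if src.startswith("organ:"):
                organs[src.split(":", 1)[1]] = series(grp[grp["source"] == src])
        datasets.append(
            PatientDataset(
                patient=patients[pid],
                blood_samples=series(grp[grp["source"] == "blood"], "concentration"),
                planar_wb_bq=series(grp[grp["source"] == "planar_wb"]),
                spect_fov_bq=series(grp[grp["source"] == "spect_fov"]),
                spect_organ_bq=organs,
            )
        )
    return datasets
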