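"""End-to-end SAD/MAD study orchestration and the 2-fold acceptance rule.

A :class:`StudyDesign` enumerates the dose grid for one compound under one
design (single ascending dose, SAD, or multiple ascending dose, MAD, with a
24 h dosing interval).  :func:`run_study` simulates every dose, computes PK
endpoints for the first and last 24 h dosing windows, and the per-enzyme
inhibition time course.  Everything is deterministic given the configuration.

Predictions are judged against observations with the 2-fold rule: a
predicted/observed ratio outside [0.5, 2] is a significant deviation (the
boundary itself passes).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

from .compounds import CompoundRecord, apply_calibration
from .nca import DEFAULT_N_TAIL, PKSummary, pk_summary
from .pbpk import ConcentrationTimeSeries, DoseRegimen, simulate
from .pd_model import PDProfile, inhibition_timecourse
from .physiology import VirtualSubject, reference_subject

logger = logging.getLogger(__name__)

#: Number of doses simulated for MAD designs (last interval ~ steady state).
MAD_N_DOSES = 10

#: Washout window (h) appended after the last dose for terminal-slope fitting.
WASHOUT_H = 48.0

#: Default SAD/MAD dose grid (mg) for four of the five compounds.
DEFAULT_DOSES_MG: tuple[float, ...] = (0.5, 1.0, 3.0, 10.0, 30.0)

#: Lorundrostat uses its clinical-trial dose grids instead.
LORUNDROSTAT_SAD_MG: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0, 100.0)
LORUNDROSTAT_MAD_MG: tuple[float, ...] = (3.0, 12.5, 50.0, 100.0)


@dataclass(frozen=True)
class StudyDesign:
    """Dose grid for one compound under SAD or MAD conditions."""

    compound: str
    design: str  # "SAD" | "MAD"
    doses: tuple[float, ...]
    interval: float = 24.0
    duration: float | None = None
    subject_weight_kg: float = 70.0

    def __post_init__(self) -> None:
        if self.design not in ("SAD", "MAD"):
            raise ValueError(f"design must be 'SAD' or 'MAD', got {self.design!r}")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise ValueError("doses must be a non-empty list of positive amounts")
        if not self.interval > 0:
            raise ValueError("interval must be > 0")
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if self.duration is None:
            object.__setattr__(self, "duration", self.default_duration)
        if self.design == "MAD" and self.duration < 5 * self.interval + WASHOUT_H:
            raise ValueError(
                "MAD duration must cover >= 5 dosing intervals plus a washout window"
            )
        if self.design == "SAD" and self.duration < self.interval + WASHOUT_H:
            raise ValueError("SAD duration must cover the 24 h window plus washout")

    @property
    def n_doses(self) -> int:
        return 1 if self.design == "SAD" else MAD_N_DOSES

    @property
    def default_duration(self) -> float:
        return (self.n_doses - 1) * self.interval + self.interval + WASHOUT_H

    def regimen(self, dose: float) -> DoseRegimen:
        return DoseRegimen(dose=dose, n_doses=self.n_doses, interval=self.interval)


@dataclass(frozen=True)
class DoseResult:
    """Everything computed for one dose of one study design."""

    dose: float
    series: ConcentrationTimeSeries
    pk_first_interval: PKSummary
    pk_last_interval: PKSummary
    pd_profile: PDProfile


@dataclass(frozen=True)
class TwoFoldResult:
    ratio: float
    passed: bool


def default_designs(subject_weight_kg: float = 70.0) -> list[StudyDesign]:
    """The ten built-in designs: SAD + MAD for each of the five compounds."""
    designs = []
    for compound in ("Baxdrostat", "BI689648", "Dexfadrostat", "LCI699"):
        designs.append(StudyDesign(compound, "SAD", DEFAULT_DOSES_MG,
                                   subject_weight_kg=subject_weight_kg))
        designs.append(StudyDesign(compound, "MAD", DEFAULT_DOSES_MG,
                                   subject_weight_kg=subject_weight_kg))
    designs.append(StudyDesign("Lorundrostat", "SAD", LORUNDROSTAT_SAD_MG,
                               subject_weight_kg=subject_weight_kg))
    designs.append(StudyDesign("Lorundrostat", "MAD", LORUNDROSTAT_MAD_MG,
                               subject_weight_kg=subject_weight_kg))
    return designs


def run_study(
    design: StudyDesign,
    library: Sequence[CompoundRecord],
    calibrated: bool = True,
    subject: VirtualSubject | None = None,
    *,
    dt_out: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_tail: int = DEFAULT_N_TAIL,
) -> dict[float, DoseResult]:
    """Simulate every dose of a design; returns one :class:`DoseResult` per dose."""
    matches = [r for r in library if r.name.lower() == design.compound.lower()]
    if not matches:
        known = ", ".join(r.name for r in library)
        raise KeyError(f"unknown compound {design.compound!r}; known compounds: {known}")
    record = apply_calibration(matches[0]) if calibrated else matches[0]
    if subject is None:
        subject = reference_subject(design.subject_weight_kg)

    cfg_hash = _config_hash(design, record, dt_out, rtol, atol, n_tail, subject)
    logger.info(
        "run_study compound=%s design=%s parameters=%s rtol=%g atol=%g config_hash=%s",
        record.name,
        design.design,
        "calibrated" if calibrated else "raw",
        rtol,
        atol,
        cfg_hash,
    )

    last_start = (design.n_doses - 1) * design.interval
    results: dict[float, DoseResult] = {}
    for dose in design.doses:
        ts = simulate(record, subject, design.regimen(dose), design.duration,
                      dt_out, rtol=rtol, atol=atol)
        results[dose] = DoseResult(
            dose=dose,
            series=ts,
            pk_first_interval=pk_summary(ts, 0.0, n_tail=n_tail),
            pk_last_interval=pk_summary(ts, last_start, n_tail=n_tail),
            pd_profile=inhibition_timecourse(ts, record),
        )
    return results


def two_fold_check(predicted: float, observed: float) -> TwoFoldResult:
    """Predicted/observed ratio with pass iff it lies within [0.5, 2].

    The boundaries are inclusive: only ratios strictly below 1/2 or strictly
    above 2 count as significant deviations.
    """
    if not observed > 0:
        raise ValueError(f"observed must be > 0, got {observed}")
    ratio = predicted / observed
    return TwoFoldResult(ratio=ratio, passed=0.5 <= ratio <= 2.0)


def summary_rows(design: StudyDesign, results: Mapping[float, DoseResult]) -> list[dict]:
    """Flatten study results into writer-ready rows (one per dose)."""
    rows = []
    for dose, res in results.items():
        rows.append(
            {
                "compound": design.compound,
                "design": design.design,
                "dose_mg": dose,
                "auc_0_24": res.pk_first_interval.auc_0_24,
                "cmax": res.pk_first_interval.cmax,
                "tmax": res.pk_first_interval.tmax,
                "t_half": res.pk_first_interval.t_half,
                "auc_0_24_last": res.pk_last_interval.auc_0_24,
                "cmax_last": res.pk_last_interval.cmax,
            }
        )
    return rows


def _config_hash(design, record, dt_out, rtol, atol, n_tail, subject) -> str:
    payload = yaml.safe_dump(
        {
            "design": [design.compound, design.design, list(design.doses),
                       design.interval, design.duration],
            "record": [record.name, record.cl_app, record.kp_scaler],
            "solver": [dt_out, rtol, atol, n_tail],
            "subject": [subject.body_weight, subject.total_volume],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
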