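"""Emax inhibition pharmacodynamics for CYP11B2 and CYP11B1.

Only free (unbound) drug is assumed active: plasma concentration (ng/mL) is
converted to free molar concentration via the fraction unbound and the
molecular weight.  Enzyme inhibition then follows a saturable
exposure–response model

    inhibition(C) = E0 + Imax * C / (C + IC50)

evaluated separately for aldosterone synthase (CYP11B2, the target) and
11β-hydroxylase (CYP11B1, the off-target whose inhibition drives side
effects).  The published form writes the response as a percentage change from
baseline, ``E = E0 - Imax*C/(C+IC50)``; this module reports the positive
inhibition magnitude (the convention used for "inhibition rate" plots), with
baseline E0 = 0 % and Imax = 100 % by default.

The selectivity index SI = IC50(CYP11B1) / IC50(CYP11B2) summarises how much
more potently a compound hits the target than the off-target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import CompoundRecord
from .nca import auc as _auc
from .pbpk import ConcentrationTimeSeries


@dataclass(frozen=True)
class PDProfile:
    """Per-enzyme inhibition time course (percent of Imax scale)."""

    times: np.ndarray
    inhibition_cyp11b2: np.ndarray
    inhibition_cyp11b1: np.ndarray
    e0: float = 0.0
    imax: float = 100.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        b2 = np.asarray(self.inhibition_cyp11b2, dtype=float)
        b1 = np.asarray(self.inhibition_cyp11b1, dtype=float)
        if b2.shape != times.shape or b1.shape != times.shape:
            raise ValueError("inhibition arrays must match the time grid")
        upper = self.e0 + self.imax
        for name, arr in (("inhibition_cyp11b2", b2), ("inhibition_cyp11b1", b1)):
            if np.any(arr < self.e0 - 1e-9) or np.any(arr > upper + 1e-9):
                raise ValueError(f"{name} outside [{self.e0}, {upper}] %")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "inhibition_cyp11b2", b2)
        object.__setattr__(self, "inhibition_cyp11b1", b1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "inhib_cyp11b2_pct": self.inhibition_cyp11b2,
                "inhib_cyp11b1_pct": self.inhibition_cyp11b1,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def free_molar_conc(cp: float | np.ndarray, f_up: float, mw: float) -> float | np.ndarray:
    """Free plasma concentration in nmol/L from total plasma ng/mL.

    ``cp * f_up`` is the free mass concentration; division by the molecular
    weight (g/mol) and the ng/mL -> nmol/L factor of 1000 gives molarity.
    """
    if not mw > 0:
        raise ValueError(f"mw must be > 0, got {mw}")
    if not 0 < f_up <= 1:
        raise ValueError(f"f_up must be in (0, 1], got {f_up}")
    cp = np.asarray(cp, dtype=float)
    if np.any(cp < 0):
        raise ValueError("plasma concentration must be >= 0")
    out = cp * f_up * 1000.0 / mw
    return float(out) if out.ndim == 0 else out


def emax_inhibition(
    c_free: float | np.ndarray,
    ic50: float,
    imax: float = 100.0,
    e0: float = 0.0,
) -> float | np.ndarray:
    """Percent inhibition at free concentration ``c_free`` (nmol/L).

    Saturable model ``e0 + imax * c / (c + ic50)``: 0 % at c = 0 (with the
    default baseline), exactly half-maximal at c = IC50, approaching
    ``e0 + imax`` asymptotically.
    """
    if not ic50 > 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    c = np.asarray(c_free, dtype=float)
    if np.any(c < 0):
        raise ValueError("free concentration must be >= 0")
    out = e0 + imax * c / (c + ic50)
    return float(out) if out.ndim == 0 else out


def selectivity_index(ic50_cyp11b1: float, ic50_cyp11b2: float) -> float:
    """SI = IC50(11β-hydroxylase) / IC50(aldosterone synthase)."""
    if not ic50_cyp11b1 > 0 or not ic50_cyp11b2 > 0:
        raise ValueError("both IC50 values must be > 0")
    return ic50_cyp11b1 / ic50_cyp11b2


def inhibition_timecourse(
    ts: ConcentrationTimeSeries,
    record: CompoundRecord,
    imax: float = 100.0,
    e0: float = 0.0,
) -> PDProfile:
    """Pointwise free-concentration conversion then Emax per enzyme."""
    c_free = free_molar_conc(ts.plasma_conc, record.f_up, record.mw)
    return PDProfile(
        times=ts.times,
        inhibition_cyp11b2=emax_inhibition(c_free, record.ic50_cyp11b2, imax, e0),
        inhibition_cyp11b1=emax_inhibition(c_free, record.ic50_cyp11b1, imax, e0),
        e0=e0,
        imax=imax,
    )


def inhibition_summary(
    ts: ConcentrationTimeSeries,
    record: CompoundRecord,
    window: tuple[float, float],
) -> dict[str, float]:
    """Peak, trough, and interval-average inhibition over a dosing window.

    All three free-concentration summaries (maximum, minimum, and the
    time-average over the window) are converted to inhibition, per enzyme.
    Reporting all three avoids committing to a single steady-state summary.
    """
    start, end = window
    mask = (ts.times >= start - 1e-9) & (ts.times <= end + 1e-9)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    c_free = free_molar_conc(ts.plasma_conc[mask], record.f_up, record.mw)
    c_avg = free_molar_conc(_auc(ts, start, end) / (end - start), record.f_up, record.mw)
    out: dict[str, float] = {}
    for enzyme, ic50 in (
        ("cyp11b2", record.ic50_cyp11b2),
        ("cyp11b1", record.ic50_cyp11b1),
    ):
        out[f"{enzyme}_peak_pct"] = float(emax_inhibition(c_free.max(), ic50))
        out[f"{enzyme}_trough_pct"] = float(emax_inhibition(c_free.min(), ic50))
        out[f"{enzyme}_avg_pct"] = float(emax_inhibition(c_avg, ic50))
    return out
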