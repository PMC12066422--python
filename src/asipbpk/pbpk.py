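"""Whole-body perfusion-limited PBPK model: ODE system, simulation, calibration.

The body is represented as 14 tissue compartments perfused in parallel
between an arterial and a mixed-venous blood pool, with the lung in series:
venous blood flows through the lung and on to the arterial pool.  Each tissue
is flow-limited — drug in tissue is assumed at equilibrium with its emergent
blood, characterised by a tissue:blood partition coefficient.  For a non-lung
tissue ``T``::

    dA_T/dt = Q_T * (A_ART / V_ART) - Q_T * A_T / (V_T * KpB_T)

and the lung obeys the same form fed from the venous pool.  ``A`` are amounts
(mg), ``V`` volumes (L), ``Q`` blood flows (L/h).  The tabulated partition
coefficients are tissue:plasma; they are converted to tissue:blood with the
blood-to-plasma ratio, ``KpB = Kp * kp_scaler / bpr``.

Oral dosing enters a depot that empties into the gut tissue with first-order
rate ``gi_ka``; systemic clearance removes drug from the venous pool at
``CL_app * C_plasma`` where ``C_plasma = (A_VEN / V_VEN) / bpr``.  The whole
system is linear and time-invariant between dose events, so doses are applied
as exact impulses to the depot with the integrator restarted at each dose
time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compounds import KP_TISSUES, CalibrationFactors, CompoundRecord, apply_calibration
from .physiology import TISSUES, VirtualSubject

#: State-vector layout: oral depot, the 14 tissues, the two blood pools, and
#: a cumulative-elimination bookkeeping compartment (closes the mass balance).
STATE_NAMES: tuple[str, ...] = ("depot", *TISSUES, "venous", "arterial", "eliminated")

_NEGATIVE_STATE_TOL = 1e-9  # relative to the largest amount seen

# Surrogates for tissues without a tabulated partition coefficient.
_KP_SURROGATES = {"stomach": "gut", "pancreas": "spleen"}


def effective_kp(record: CompoundRecord, tissue: str) -> float:
    """Scaled tissue:plasma partition coefficient for any of the 14 tissues.

    The 11 tabulated tissues use their own value; stomach borrows gut's,
    pancreas borrows spleen's, and rest_of_body uses the mean of the 11
    tabulated values.  Each is multiplied by the record's ``kp_scaler``.
    """
    if tissue in record.kp:
        base = record.kp[tissue]
    elif tissue in _KP_SURROGATES:
        base = record.kp[_KP_SURROGATES[tissue]]
    elif tissue == "rest_of_body":
        base = float(np.mean([record.kp[t] for t in KP_TISSUES]))
    else:
        raise ValueError(
            f"unknown tissue {tissue!r}; expected one of {', '.join(TISSUES)}"
        )
    return base * record.kp_scaler


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dose schedule: ``dose`` mg given ``n_doses`` times every ``interval`` h."""

    dose: float
    n_doses: int = 1
    interval: float = 24.0
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")
        if self.n_doses > 1 and not self.interval > 0:
            raise ValueError("interval must be > 0 for multiple doses")
        if self.route != "oral":
            raise ValueError(f"only oral dosing is supported, got {self.route!r}")

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(k * self.interval for k in range(self.n_doses))


@dataclass(frozen=True)
class ConcentrationTimeSeries:
    """Simulated trajectory: plasma concentration plus compartment amounts.

    ``times`` (h) start at 0 and are strictly increasing; ``plasma_conc`` is
    venous plasma concentration in ng/mL; ``amounts`` is a (n_times, n_state)
    array of compartment amounts in mg, columns ordered as ``STATE_NAMES``.
    Values at a dose time are post-dose.
    """

    times: np.ndarray
    plasma_conc: np.ndarray
    amounts: np.ndarray
    state_names: tuple[str, ...] = STATE_NAMES

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.plasma_conc, dtype=float)
        amounts = np.asarray(self.amounts, dtype=float)
        if times.ndim != 1 or times.size == 0 or times[0] != 0.0:
            raise ValueError("times must be a non-empty 1-D grid starting at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if conc.shape != times.shape or amounts.shape != (times.size, len(self.state_names)):
            raise ValueError("plasma_conc/amounts shapes inconsistent with times")
        scale = max(amounts.max(initial=0.0), 1.0)
        if amounts.min(initial=0.0) < -_NEGATIVE_STATE_TOL * scale:
            raise ValueError(
                f"negative compartment amount beyond tolerance: min={amounts.min()}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "plasma_conc", conc)
        object.__setattr__(self, "amounts", np.clip(amounts, 0.0, None))

    def amount(self, compartment: str) -> np.ndarray:
        return self.amounts[:, self.state_names.index(compartment)]

    @property
    def total_amount(self) -> np.ndarray:
        """Total mass (mg) over all compartments including eliminated."""
        return self.amounts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times, "plasma_ng_per_mL": self.plasma_conc})
        for i, name in enumerate(self.state_names):
            df[f"{name}_mg"] = self.amounts[:, i]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PBPKSystem:
    """Assembled linear ODE system ``dy/dt = M y + b`` for one compound."""

    record: CompoundRecord
    subject: VirtualSubject
    matrix: np.ndarray
    forcing: np.ndarray
    state_names: tuple[str, ...] = STATE_NAMES

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:  # noqa: ARG002
        return self.matrix @ y + self.forcing

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:  # noqa: ARG002
        return self.matrix

    def plasma_conc_ng_per_ml(self, amounts: np.ndarray) -> np.ndarray:
        """Venous plasma concentration (ng/mL) from state amounts (mg)."""
        i_ven = self.state_names.index("venous")
        c_blood = np.asarray(amounts)[..., i_ven] / self.subject.venous_volume
        return c_blood / self.record.bpr * 1000.0  # mg/L -> ng/mL


def build_odes(
    record: CompoundRecord,
    subject: VirtualSubject,
    infusion_rate: float = 0.0,
) -> PBPKSystem:
    """Assemble the whole-body system for one compound on one subject.

    ``infusion_rate`` (mg/h into the venous pool) exists as a test-harness
    mode for verifying the clearance steady state; user-facing dosing is oral.
    The subject's flow-balance invariant is re-checked here so an imbalanced
    hand-built subject is rejected at build time.
    """
    co = subject.cardiac_output
    non_lung_flow = sum(t.blood_flow for t in subject.tissues if t.name != "lung")
    if not np.isclose(non_lung_flow, co, rtol=1e-9):
        raise ValueError("flow-imbalanced subject: non-lung flows must sum to cardiac output")

    idx = {name: i for i, name in enumerate(STATE_NAMES)}
    n = len(STATE_NAMES)
    m = np.zeros((n, n))
    i_ven, i_art, i_dep, i_elim = idx["venous"], idx["arterial"], idx["depot"], idx["eliminated"]

    # oral absorption: depot -> gut tissue
    m[i_dep, i_dep] -= record.gi_ka
    m[idx["gut"], i_dep] += record.gi_ka

    for tissue in subject.tissues:
        i_t = idx[tissue.name]
        kpb = effective_kp(record, tissue.name) / record.bpr  # tissue:blood
        out_coef = tissue.blood_flow / (tissue.volume * kpb)
        if tissue.name == "lung":
            # venous -> lung -> arterial
            m[i_t, i_ven] += tissue.blood_flow / subject.venous_volume
            m[i_ven, i_ven] -= tissue.blood_flow / subject.venous_volume
            m[i_t, i_t] -= out_coef
            m[i_art, i_t] += out_coef
        else:
            # arterial -> tissue -> venous
            m[i_t, i_art] += tissue.blood_flow / subject.arterial_volume
            m[i_art, i_art] -= tissue.blood_flow / subject.arterial_volume
            m[i_t, i_t] -= out_coef
            m[i_ven, i_t] += out_coef

    # systemic clearance on venous plasma concentration
    k_el = record.cl_app / (subject.venous_volume * record.bpr)
    m[i_ven, i_ven] -= k_el
    m[i_elim, i_ven] += k_el

    forcing = np.zeros(n)
    forcing[i_ven] = infusion_rate
    return PBPKSystem(record=record, subject=subject, matrix=m, forcing=forcing)


def simulate(
    record: CompoundRecord,
    subject: VirtualSubject,
    regimen: DoseRegimen,
    t_end: float,
    dt_out: float = 0.1,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    infusion_rate: float = 0.0,
    method: str = "LSODA",
) -> ConcentrationTimeSeries:
    """Integrate the model over ``[0, t_end]`` h under a dose regimen.

    Each dose is an exact impulse to the depot at ``k * interval``; the
    integrator restarts at every dose time.  Output is sampled every
    ``dt_out`` h (samples at a dose time are post-dose).  Tolerances default
    to rtol 1e-8 / atol 1e-10 and are fixed per run for reproducibility.
    """
    if not dt_out > 0:
        raise ValueError(f"dt_out must be > 0, got {dt_out}")
    dose_times = regimen.dose_times
    if t_end < dose_times[-1]:
        raise ValueError(
            f"t_end={t_end} h does not cover the last dose at {dose_times[-1]} h"
        )

    system = build_odes(record, subject, infusion_rate=infusion_rate)
    n_steps = int(round(t_end / dt_out))
    grid = np.linspace(0.0, n_steps * dt_out, n_steps + 1)
    if grid[-1] < t_end - 1e-9:
        grid = np.append(grid, t_end)

    i_dep = STATE_NAMES.index("depot")
    boundaries = list(dose_times) + [grid[-1]]
    y = np.zeros(len(STATE_NAMES))
    out = np.empty((grid.size, len(STATE_NAMES)))
    filled = np.zeros(grid.size, dtype=bool)

    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        y = y.copy()
        y[i_dep] += regimen.dose  # impulse at segment start
        # post-dose sample exactly at the segment start, if on the grid
        at_start = np.isclose(grid, seg_start, rtol=0.0, atol=1e-9)
        out[at_start] = y
        filled |= at_start
        if seg_end <= seg_start + 1e-12:
            continue
        mask = (grid > seg_start + 1e-9) & (grid <= seg_end + 1e-9)
        # evaluate at the in-segment grid points plus the segment end (needed
        # to chain the next impulse); grid points may carry float noise, so
        # clamp them into the integration span
        t_eval = np.clip(grid[mask], seg_start, seg_end)
        if t_eval.size == 0 or abs(t_eval[-1] - seg_end) > 1e-12:
            t_eval = np.append(t_eval, seg_end)
            extra_end = True
        else:
            extra_end = False
        sol = solve_ivp(
            system.rhs,
            (seg_start, seg_end),
            y,
            method=method,
            t_eval=t_eval,
            jac=system.jacobian,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed for {record.name} in [{seg_start}, {seg_end}] h: "
                f"{sol.message}; state={dict(zip(STATE_NAMES, y))}"
            )
        n_grid = t_eval.size - 1 if extra_end else t_eval.size
        if n_grid:
            out[mask] = sol.y.T[:n_grid]
            filled |= mask
        y = sol.y[:, -1]

    if not filled.all():  # pragma: no cover - grid construction guarantees coverage
        raise RuntimeError("internal error: output grid not fully covered")

    return ConcentrationTimeSeries(
        times=grid,
        plasma_conc=system.plasma_conc_ng_per_ml(out),
        amounts=out,
    )


# ---------------------------------------------------------------------------
# observed-data IO and grid-search calibration
# ---------------------------------------------------------------------------

def read_observed_csv(path: str | Path) -> pd.DataFrame:
    """Read a 2-column observed table (``time_h``, ``conc_ng_per_mL``)."""
    df = pd.read_csv(path)
    required = {"time_h", "conc_ng_per_mL"}
    if not required.issubset(df.columns):
        raise ValueError(f"observed CSV must have columns {sorted(required)}")
    return df[["time_h", "conc_ng_per_mL"]].astype(float)


def calibrate_to_observed(
    record: CompoundRecord,
    subject: VirtualSubject,
    regimen: DoseRegimen,
    observed: pd.DataFrame,
    kp_factors: Sequence[float],
    cl_divisors: Sequence[float],
    *,
    dt_out: float = 0.25,
    t_end: float | None = None,
) -> CalibrationFactors:
    """Grid-search the calibration pair minimising RMSE against observed data.

    ``observed`` needs columns ``time_h`` and ``conc_ng_per_mL`` with at
    least 3 points inside the simulated window.  Ties break deterministically
    toward the smallest ``kp_factor``, then the smallest ``cl_divisor``.
    """
    kp_factors = sorted(float(k) for k in kp_factors)
    cl_divisors = sorted(float(c) for c in cl_divisors)
    if not kp_factors or not cl_divisors:
        raise ValueError("calibration grid must be non-empty")
    obs = observed.sort_values("time_h")
    t_obs = obs["time_h"].to_numpy(dtype=float)
    c_obs = obs["conc_ng_per_mL"].to_numpy(dtype=float)
    if t_end is None:
        t_end = max(float(t_obs.max()), regimen.dose_times[-1] + regimen.interval)
    in_window = (t_obs >= 0) & (t_obs <= t_end)
    if in_window.sum() < 3:
        raise ValueError("need at least 3 observed points inside the simulated window")
    t_obs, c_obs = t_obs[in_window], c_obs[in_window]

    best: tuple[float, CalibrationFactors] | None = None
    for kp_f, cl_d in itertools.product(kp_factors, cl_divisors):
        factors = CalibrationFactors(kp_factor=kp_f, cl_divisor=cl_d)
        ts = simulate(apply_calibration(record, factors), subject, regimen, t_end, dt_out)
        pred = np.interp(t_obs, ts.times, ts.plasma_conc)
        rmse = float(np.sqrt(np.mean((pred - c_obs) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, factors)
    assert best is not None
    return best[1]
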