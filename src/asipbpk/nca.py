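"""Non-compartmental PK endpoints and goodness-of-fit metrics.

Endpoints follow standard NCA conventions: linear-trapezoid AUC over
[0, 24] h (with linear interpolation of a boundary sample when 24 h is not a
grid point), maximum observed concentration and its earliest time, and a
terminal half-life from an ordinary least-squares fit of log concentration
over the last post-peak samples.  Fit metrics compare a predicted against an
observed series on a shared grid: MAE, MSE, RMSE and R² about the observed
mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pbpk import ConcentrationTimeSeries

#: Default number of post-peak samples used for the terminal-slope fit.
DEFAULT_N_TAIL = 5


@dataclass(frozen=True)
class PKSummary:
    """Single-profile PK endpoints (Cmax ng/mL, Tmax h, AUC ng·h/mL, T1/2 h)."""

    auc_0_24: float
    cmax: float
    tmax: float
    t_half: float

    def __post_init__(self) -> None:
        for name in ("auc_0_24", "cmax", "tmax", "t_half"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class FitMetrics:
    """Prediction-error summary: MAE/MSE/RMSE (concentration units) and R²."""

    mae: float
    mse: float
    rmse: float
    r2: float

    def __post_init__(self) -> None:
        if not np.isclose(self.rmse, np.sqrt(self.mse)):
            raise ValueError("rmse must equal sqrt(mse)")
        if self.mae > self.rmse * (1 + 1e-12):
            raise ValueError("mae cannot exceed rmse")
        if np.isfinite(self.r2) and self.r2 > 1:
            raise ValueError("r2 cannot exceed 1")


def auc(ts: ConcentrationTimeSeries, start: float, end: float) -> float:
    """Linear-trapezoid area of plasma concentration over ``[start, end]`` h.

    Boundary samples are linearly interpolated when ``start``/``end`` fall
    between grid points.
    """
    if start < ts.times[0] or end > ts.times[-1]:
        raise ValueError(
            f"window [{start}, {end}] h outside the simulated span "
            f"[{ts.times[0]}, {ts.times[-1]}] h"
        )
    if not end > start:
        raise ValueError("end must exceed start")
    inner = (ts.times > start) & (ts.times < end)
    t = np.concatenate(([start], ts.times[inner], [end]))
    c = np.concatenate(
        (
            [np.interp(start, ts.times, ts.plasma_conc)],
            ts.plasma_conc[inner],
            [np.interp(end, ts.times, ts.plasma_conc)],
        )
    )
    return float(np.trapezoid(c, t))


def auc_0_24(ts: ConcentrationTimeSeries) -> float:
    """AUC over the first 24 h (ng·h/mL); the series must span >= 24 h."""
    if ts.times[-1] < 24.0:
        raise ValueError(f"series spans only {ts.times[-1]} h; need >= 24 h")
    return auc(ts, 0.0, 24.0)


def cmax_tmax(ts: ConcentrationTimeSeries) -> tuple[float, float]:
    """Maximum sampled plasma concentration and its earliest attaining time."""
    i = int(np.argmax(ts.plasma_conc))  # argmax returns the earliest maximum
    return float(ts.plasma_conc[i]), float(ts.times[i])


def terminal_half_life(ts: ConcentrationTimeSeries, n_tail: int = DEFAULT_N_TAIL) -> float:
    """Terminal half-life (h) from a log-linear fit of the last samples.

    Uses the last ``n_tail`` post-Tmax samples with positive concentration;
    ``t_half = ln 2 / k`` where ``-k`` is the OLS slope of ln(conc) on time.
    Raises if the tail is too short or shows no decline.
    """
    if n_tail < 2:
        raise ValueError("n_tail must be >= 2")
    _, tmax = cmax_tmax(ts)
    mask = (ts.times > tmax) & (ts.plasma_conc > 0)
    if mask.sum() < n_tail:
        raise ValueError(
            f"need >= {n_tail} post-peak samples with positive concentration, "
            f"got {int(mask.sum())}"
        )
    t = ts.times[mask][-n_tail:]
    logc = np.log(ts.plasma_conc[mask][-n_tail:])
    slope = stats.linregress(t, logc).slope
    if slope >= 0:
        raise ValueError("no terminal phase: tail concentrations are not declining")
    return float(np.log(2.0) / -slope)


def pk_summary(
    ts: ConcentrationTimeSeries,
    window_start: float = 0.0,
    n_tail: int = DEFAULT_N_TAIL,
) -> PKSummary:
    """Endpoints for the 24 h window starting at ``window_start``.

    ``tmax`` is reported relative to the window start (time since dose).  The
    half-life is fitted on the tail of samples from ``window_start`` onward,
    using everything to the end of the series (a washout tail, when present,
    sharpens the terminal-slope estimate).
    """
    sub = _window(ts, window_start)
    return PKSummary(
        auc_0_24=auc_0_24(sub),
        cmax=cmax_tmax(sub)[0],
        tmax=cmax_tmax(sub)[1],
        t_half=terminal_half_life(sub, n_tail=n_tail),
    )


def _window(ts: ConcentrationTimeSeries, start: float) -> ConcentrationTimeSeries:
    if start == 0.0:
        return ts
    mask = ts.times >= start - 1e-9
    return ConcentrationTimeSeries(
        times=ts.times[mask] - ts.times[mask][0],
        plasma_conc=ts.plasma_conc[mask],
        amounts=ts.amounts[mask],
        state_names=ts.state_names,
    )


def fit_metrics(pred: np.ndarray, obs: np.ndarray) -> FitMetrics:
    """MAE/MSE/RMSE/R² of predictions against observations on a shared grid.

    R² is ``1 - SSres/SStot`` with SStot about the observed mean; for a
    constant observed series it is undefined and reported as NaN with a
    warning.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("pred and obs must be equal-length 1-D arrays with >= 2 points")
    err = pred - obs
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        warnings.warn("observed series is constant; R² is undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / sstot
    return FitMetrics(mae=mae, mse=mse, rmse=float(np.sqrt(mse)), r2=r2)


def write_summary_csv(rows: list[dict], path: str | Path) -> None:
    """Write PK summaries, one row per compound × dose × design."""
    pd.DataFrame(rows).to_csv(path, index=False)
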