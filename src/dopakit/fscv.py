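"""Fast-scan cyclic voltammetry (FSCV) dopamine-release kinetics.

Works on extracted oxidation-current or dopamine-concentration time series
(one value per voltammetric scan, 10 Hz for the standard 100 ms scan
repetition).  Covers electrode calibration against dopamine standards,
current-to-concentration conversion, evoked-release peak amplitude, and the
single-exponential decay constant τ of the falling phase,

    C(t) = baseline + A * exp(-(t - t_peak) / τ),

a standard proxy for dopamine reuptake rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize as _optimize

__all__ = [
    "CalibrationStandard",
    "Calibration",
    "FscvTrace",
    "DecayFit",
    "FscvError",
    "DecayFitError",
    "calibrate",
    "to_concentration",
    "peak_amplitude",
    "fit_decay",
]

CURRENT_NA = "CURRENT_NA"
CONC_UM = "CONC_UM"


class FscvError(ValueError):
    pass


class DecayFitError(FscvError):
    """Raised when the exponential decay fit fails or is degenerate."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: known dopamine concentration vs measured current."""

    concentration_um: float
    current_na: float


@dataclass
class Calibration:
    """Electrode response line: current = slope * concentration + intercept.

    ``range_um`` records the concentration span of the standards (electrodes
    are typically calibrated in 0.1-2 µM dopamine); conversions outside the
    range are flagged, never clipped.
    """

    slope_na_per_um: float
    intercept_na: float
    r2: float
    range_um: tuple[float, float]


@dataclass
class FscvTrace:
    """Evoked-release time series in nA (raw) or µM (calibrated)."""

    time_s: np.ndarray
    value: np.ndarray
    units: str
    sample_rate_hz: float
    stim_time_s: float
    out_of_range: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.time_s) != len(self.value):
            raise FscvError("time and value lengths differ")
        if len(self.time_s) > 1 and not (np.diff(self.time_s) > 0).all():
            raise FscvError("time_s must be strictly increasing")
        if self.units not in (CURRENT_NA, CONC_UM):
            raise FscvError(f"unknown units: {self.units!r}")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class DecayFit:
    """Fitted post-peak exponential decay."""

    tau_s: float
    amplitude_um: float
    baseline_um: float
    t_peak_s: float
    fit_window: tuple[float, float]
    r2: float
    n_points: int


# ---------------------------------------------------------------------------


def calibrate(standards: Sequence[CalibrationStandard]) -> Calibration:
    """Least-squares electrode calibration line from dopamine standards.

    Requires at least two distinct concentrations; a negative fitted slope
    signals an electrode fault and raises.
    """
    conc = np.array([s.concentration_um for s in standards], dtype=float)
    cur = np.array([s.current_na for s in standards], dtype=float)
    if len(conc) < 2:
        raise FscvError("need >= 2 calibration standards")
    if np.ptp(conc) == 0:
        raise FscvError("calibration standards have identical concentrations")
    # OLS by hand keeps the two-point case exact.
    A = np.vstack([conc, np.ones_like(conc)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, cur, rcond=None)
    if slope <= 0:
        raise FscvError(f"negative or zero fitted slope ({slope:.4g} nA/µM)")
    pred = slope * conc + intercept
    ss_tot = float(((cur - cur.mean()) ** 2).sum())
    ss_res = float(((cur - pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return Calibration(
        slope_na_per_um=float(slope),
        intercept_na=float(intercept),
        r2=r2,
        range_um=(float(conc.min()), float(conc.max())),
    )


def to_concentration(trace: FscvTrace, cal: Calibration) -> FscvTrace:
    """Convert a current trace to µM: C = (I - intercept) / slope.

    Samples whose concentration falls outside the calibration range are
    flagged in ``out_of_range`` (values are not clipped).
    """
    if trace.units != CURRENT_NA:
        raise FscvError(f"expected units {CURRENT_NA}, got {trace.units}")
    conc = (trace.value - cal.intercept_na) / cal.slope_na_per_um
    lo, hi = cal.range_um
    flags = (conc < lo) | (conc > hi)
    return FscvTrace(
        time_s=trace.time_s.copy(),
        value=conc,
        units=CONC_UM,
        sample_rate_hz=trace.sample_rate_hz,
        stim_time_s=trace.stim_time_s,
        out_of_range=flags,
    )


def _require_um(trace: FscvTrace, op: str) -> None:
    if trace.units != CONC_UM:
        raise FscvError(f"{op} requires a µM trace, got units {trace.units}")


def _baseline(trace: FscvTrace, baseline_window_s: float = 1.0) -> float:
    pre = (trace.time_s >= trace.stim_time_s - baseline_window_s) & (
        trace.time_s < trace.stim_time_s
    )
    if not pre.any():
        raise FscvError("no samples in the pre-stimulus baseline window")
    return float(trace.value[pre].mean())


def peak_amplitude(
    trace: FscvTrace,
    search_window_s: float = 2.0,
    baseline_window_s: float = 1.0,
) -> tuple[float, float]:
    """Evoked peak above baseline and its time.

    Baseline is the mean over ``baseline_window_s`` preceding the stimulus;
    the peak is the maximum within ``search_window_s`` after it.
    """
    _require_um(trace, "peak_amplitude")
    base = _baseline(trace, baseline_window_s)
    win = (trace.time_s >= trace.stim_time_s) & (
        trace.time_s <= trace.stim_time_s + search_window_s
    )
    if not win.any():
        raise FscvError("post-stimulus search window contains no samples")
    idx = np.flatnonzero(win)
    k = idx[int(np.argmax(trace.value[idx]))]
    return float(trace.value[k] - base), float(trace.time_s[k])


def fit_decay(
    trace: FscvTrace,
    t_peak_s: Optional[float] = None,
    fit_fraction: float = 0.1,
    baseline_window_s: float = 1.0,
    search_window_s: float = 2.0,
    max_iterations: int = 2000,
) -> DecayFit:
    """Single-exponential least-squares fit of the post-peak decay.

    The fit window runs from the peak to the first sample at or below
    baseline + ``fit_fraction`` * amplitude (default 10% of the amplitude),
    or the end of the trace.  Initial values: A0 = measured peak amplitude,
    τ0 = time-to-half-peak / ln 2, baseline0 = pre-stimulus mean.  Raises
    :class:`DecayFitError` for degenerate inputs (amplitude at the noise
    floor) or non-convergence.
    """
    _require_um(trace, "fit_decay")
    base0 = _baseline(trace, baseline_window_s)
    if t_peak_s is None:
        _, t_peak_s = peak_amplitude(trace, search_window_s, baseline_window_s)
    i_peak = int(np.searchsorted(trace.time_s, t_peak_s))
    i_peak = min(i_peak, len(trace) - 1)
    peak_val = float(trace.value[i_peak])
    amp0 = peak_val - base0

    pre = (trace.time_s >= trace.stim_time_s - baseline_window_s) & (
        trace.time_s < trace.stim_time_s
    )
    noise_sd = float(trace.value[pre].std()) if pre.sum() >= 2 else 0.0
    if amp0 <= max(3.0 * noise_sd, 1e-12):
        raise DecayFitError(
            "degenerate fit: amplitude at or below the noise floor",
            {"amplitude": amp0, "noise_sd": noise_sd},
        )

    # fit window: peak -> first sample at/below baseline + fit_fraction * A
    floor = base0 + fit_fraction * amp0
    tail = trace.value[i_peak:]
    below = np.flatnonzero(tail <= floor)
    i_end = i_peak + int(below[0]) + 1 if below.size else len(trace)
    t = trace.time_s[i_peak:i_end] - trace.time_s[i_peak]
    y = trace.value[i_peak:i_end]
    if len(t) < 5:
        raise DecayFitError(
            f"fit window has {len(t)} samples; need >= 5",
            {"window": (float(trace.time_s[i_peak]), float(trace.time_s[i_end - 1]))},
        )

    half = base0 + 0.5 * amp0
    below_half = np.flatnonzero(y <= half)
    t_half = float(t[below_half[0]]) if below_half.size else float(t[-1]) / 2.0
    tau0 = max(t_half / math.log(2.0), 1.0 / trace.sample_rate_hz)

    def model(tt, A, tau, b):
        return b + A * np.exp(-tt / tau)

    try:
        popt, _ = _optimize.curve_fit(
            model,
            t,
            y,
            p0=[amp0, tau0, base0],
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=max_iterations,
        )
    except RuntimeError as exc:
        raise DecayFitError(
            f"decay fit did not converge: {exc}",
            {"p0": [amp0, tau0, base0], "n_points": len(t)},
        ) from exc
    A, tau, b = (float(v) for v in popt)
    pred = model(t, A, tau, b)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - pred) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(
        tau_s=tau,
        amplitude_um=A,
        baseline_um=b,
        t_peak_s=float(trace.time_s[i_peak]),
        fit_window=(float(trace.time_s[i_peak]), float(trace.time_s[i_end - 1])),
        r2=r2,
        n_points=len(t),
    )
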