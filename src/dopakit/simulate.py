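"""Synthetic recordings with known ground truth.

Three generators, one per data stream the analysis modules consume:

* :func:`gen_photometry` -- two-channel fiber-photometry traces with shared
  photobleaching and motion artifacts, Poisson-timed dopamine transients in
  the sensor channel only, and a duty-cycle recording mask.
* :func:`gen_fscv` -- electrically evoked dopamine transients with known
  peak amplitude and exponential decay constant.
* :func:`gen_session` -- operant self-administration event logs produced by
  a stochastic agent responding under FR1, multiple-dose or progressive-ratio
  schedule rules.

Every generator plants its ground truth (event times, amplitudes, the full
parameter set) in a :class:`SyntheticGroundTruth` so downstream estimators
can be scored against what was actually simulated.  A single integer seed
drives one dedicated random generator per call; identical (params, seed)
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy import signal as _signal
from scipy import ndimage as _ndimage

from .behavior import (
    OperantEventLog,
    ScheduleSpec,
    infusion_duration,
    pr_requirement,
)
from .fscv import CONC_UM, FscvTrace
from .photometry import PhotometryTrace

import pandas as pd

__all__ = [
    "PhotometrySimParams",
    "FscvSimParams",
    "AgentParams",
    "SyntheticGroundTruth",
    "SimulationError",
    "gen_photometry",
    "gen_fscv",
    "gen_session",
    "duty_cycle_mask",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PhotometrySimParams:
    """Photometry generator settings.

    The acquisition constants mirror a dual-wavelength lock-in photometry
    rig: 12 ksps decimated by 100 (120 samples/s), recording in a 5 min
    on / 1 min off duty cycle, signals low-pass filtered at 6 Hz (emulated
    by bandlimiting the channel noise).  Transient amplitude and kinetics
    for GRAB-DA class sensors in vivo are not pinned by published numbers;
    the defaults below (5% ΔF/F, 50 ms rise, 500 ms decay) are placeholder
    values in the physiological range and are echoed into the ground truth.
    """

    duration_s: float = 1200.0
    sample_rate_hz: float = 120.0
    baseline_f: float = 100.0          # raw fluorescence baseline, a.u.
    bleach_tau_s: float = 1500.0       # photobleaching time constant
    bleach_frac: float = 0.3           # fraction of fluorescence that bleaches
    motion_sd: float = 0.5             # shared motion artifact SD, a.u.
    motion_tau_s: float = 0.1          # motion smoothing timescale
    noise_sd_465: float = 0.3          # sensor channel noise SD, a.u.
    noise_sd_560: float = 0.3          # control channel noise SD, a.u.
    noise_bandwidth_hz: float = 6.0    # acquisition low-pass bandwidth
    transient_rate_hz: float = 0.05    # Poisson dopamine transient rate
    transient_amp: float = 0.05        # planted amplitude, ΔF/F units
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.5
    control_gain: float = 0.7          # shared-component gain into 560 nm
    duty_on_s: float = 300.0
    duty_off_s: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise SimulationError("duration and sample rate must be positive")
        if not (0 <= self.bleach_frac < 1):
            raise SimulationError("bleach_frac must be in [0, 1)")
        if not self.rise_tau_s < self.decay_tau_s:
            raise SimulationError("rise_tau_s must be < decay_tau_s")
        if self.duty_on_s <= 0 or self.duty_off_s < 0:
            raise SimulationError("duty_on_s > 0 and duty_off_s >= 0 required")


@dataclass(frozen=True)
class FscvSimParams:
    """Evoked-release generator: stimulation at ``stim_time_s`` produces a
    transient rising over ``rise_time_s`` to ``peak_um`` above baseline and
    decaying exponentially with ``decay_tau_s``.  ``n_pulses=5`` with
    ``pulse_interval_s=0.01`` emulates a 5-pulse 100 Hz train by kernel
    superposition."""

    duration_s: float = 15.0
    sample_rate_hz: float = 10.0       # one scan per 100 ms
    stim_time_s: float = 5.0
    peak_um: float = 1.0
    decay_tau_s: float = 0.5
    rise_time_s: float = 0.2
    baseline_um: float = 0.0
    noise_sd_um: float = 0.02
    n_pulses: int = 1
    pulse_interval_s: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.stim_time_s < self.duration_s):
            raise SimulationError("stim_time_s must lie within the recording")
        if self.peak_um < 0:
            raise SimulationError("peak_um must be >= 0")
        if self.decay_tau_s <= 0:
            raise SimulationError("decay_tau_s must be positive")
        if self.n_pulses < 1:
            raise SimulationError("n_pulses must be >= 1")


@dataclass(frozen=True)
class AgentParams:
    """Stochastic operant agent.

    The agent pokes the inactive port as a Poisson process at
    ``inactive_rate_hz`` and the active port at an exploratory floor
    (``inactive_rate_hz``) plus a reward-maintained component
    ``base_rate_hz * d^h / (d^h + d50^h)`` coupling response rate to unit
    dose d (Hill exponent h).  After each infusion the agent pauses for
    ``post_infusion_pause_s * dose`` seconds (satiety, scaling with dose).
    On PR schedules each counted poke carries a ``quit_hazard_per_required_poke``
    probability of abandoning the session.  Setting
    ``deterministic_interval_s`` replaces the stochastic active-poke stream
    with a metronome (used for worked examples and cap checks).

    This agent exists to exercise the schedule analytics with plausible
    inverted-U dose behavior, not to reproduce animal response rates.
    """

    base_rate_hz: float = 0.1
    inactive_rate_hz: float = 0.002
    post_infusion_pause_s: float = 150.0   # seconds per mg/kg unit dose
    quit_hazard_per_required_poke: float = 0.01
    reinforcement_d50_mg_kg: float = 0.15
    reinforcement_hill: float = 2.0
    deterministic_interval_s: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            self.base_rate_hz < 0
            or self.inactive_rate_hz < 0
            or self.post_infusion_pause_s < 0
            or not (0 <= self.quit_hazard_per_required_poke <= 1)
        ):
            raise SimulationError("agent rates must be >= 0; hazard in [0, 1]")

    def active_rate(self, dose_mg_kg: float) -> float:
        if dose_mg_kg <= 0:
            return self.inactive_rate_hz
        d = dose_mg_kg**self.reinforcement_hill
        d50 = self.reinforcement_d50_mg_kg**self.reinforcement_hill
        return self.inactive_rate_hz + self.base_rate_hz * d / (d + d50)


@dataclass
class SyntheticGroundTruth:
    """Planted events and the generator parameters that produced a dataset."""

    event_times_s: np.ndarray
    event_amps: np.ndarray
    params_echo: dict
    seed: int

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.event_amps = np.asarray(self.event_amps, dtype=float)
        if len(self.event_times_s) > 1 and not (
            np.diff(self.event_times_s) > 0
        ).all():
            raise SimulationError("ground-truth event times must increase")


# ---------------------------------------------------------------------------
# Photometry


def duty_cycle_mask(
    t: np.ndarray, duty_on_s: float, duty_off_s: float
) -> np.ndarray:
    """Recording mask for a duty cycle of ``duty_on_s`` on / ``duty_off_s`` off."""
    if duty_off_s == 0:
        return np.ones(len(t), dtype=bool)
    return (t % (duty_on_s + duty_off_s)) < duty_on_s


def _bandlimited_noise(
    rng: np.random.Generator,
    n: int,
    sd: float,
    fs: float,
    bandwidth_hz: float,
) -> np.ndarray:
    """White Gaussian noise low-pass filtered to the acquisition bandwidth,
    rescaled to the requested SD."""
    if sd == 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    if bandwidth_hz and bandwidth_hz < fs / 2.0:
        b, a = _signal.butter(4, bandwidth_hz / (fs / 2.0))
        x = _signal.filtfilt(b, a, x)
        x_sd = x.std()
        if x_sd > 0:
            x = x / x_sd
    return sd * x


def _transient_kernel_unit(
    dt: np.ndarray, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak."""
    g = (1.0 - np.exp(-dt / rise_tau)) * np.exp(-dt / decay_tau)
    t_peak = rise_tau * math.log(1.0 + decay_tau / rise_tau)
    g_max = (1.0 - math.exp(-t_peak / rise_tau)) * math.exp(-t_peak / decay_tau)
    return g / g_max


def gen_photometry(
    params: PhotometrySimParams, seed: int = 0
) -> tuple[PhotometryTrace, SyntheticGroundTruth]:
    """Simulate a two-channel photometry recording.

    Signal model (t in seconds, s(t) the planted transient sum in ΔF/F
    units, m(t) the shared motion artifact, n_ch bandlimited channel noise):

        F465(t) = B * bleach(t) * (1 + s(t)) + m(t) + n465(t)
        F560(t) = g * (B * bleach(t) + m(t)) + n560(t)
        bleach(t) = (1 - f) + f * exp(-t / τ_bleach)

    Transients are planted multiplicatively on the bleach envelope so their
    planted amplitudes are exactly in ΔF/F units; each is a
    difference-of-exponentials kernel normalised to unit peak.  Samples in
    duty-cycle off periods are masked and set to NaN.
    """
    rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    mask = duty_cycle_mask(t, params.duty_on_s, params.duty_off_s)

    bleach = (1.0 - params.bleach_frac) + params.bleach_frac * np.exp(
        -t / params.bleach_tau_s
    )

    # Poisson-timed transients over the whole session
    event_times: list[float] = []
    if params.transient_rate_hz > 0:
        tt = rng.exponential(1.0 / params.transient_rate_hz)
        while tt < params.duration_s:
            event_times.append(tt)
            tt += rng.exponential(1.0 / params.transient_rate_hz)
    event_times_arr = np.array(event_times)
    event_amps = np.full(len(event_times), params.transient_amp)

    s = np.zeros(n)
    span = params.rise_tau_s + 8.0 * params.decay_tau_s
    for t0, amp in zip(event_times, event_amps):
        i0 = int(math.ceil(t0 * fs))
        i1 = min(n, int(math.ceil((t0 + span) * fs)))
        if i0 >= n:
            continue
        dt = t[i0:i1] - t0
        s[i0:i1] += amp * _transient_kernel_unit(
            dt, params.rise_tau_s, params.decay_tau_s
        )

    if params.motion_sd > 0:
        motion = _ndimage.gaussian_filter1d(
            rng.standard_normal(n), params.motion_tau_s * fs
        )
        m_sd = motion.std()
        motion = params.motion_sd * motion / m_sd if m_sd > 0 else motion
    else:
        motion = np.zeros(n)

    shared = params.baseline_f * bleach
    f465 = (
        shared * (1.0 + s)
        + motion
        + _bandlimited_noise(rng, n, params.noise_sd_465, fs, params.noise_bandwidth_hz)
    )
    f560 = params.control_gain * (shared + motion) + _bandlimited_noise(
        rng, n, params.noise_sd_560, fs, params.noise_bandwidth_hz
    )
    f465[~mask] = np.nan
    f560[~mask] = np.nan

    trace = PhotometryTrace(
        time_s=t, f465=f465, f560=f560, mask=mask, sample_rate_hz=fs
    )
    truth = SyntheticGroundTruth(
        event_times_s=event_times_arr,
        event_amps=event_amps,
        params_echo=asdict(params),
        seed=seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# FSCV


def _fscv_kernel(
    t: np.ndarray, t0: float, peak: float, rise: float, tau: float
) -> np.ndarray:
    """Linear rise over ``rise`` seconds to ``peak``, then exponential decay."""
    y = np.zeros(len(t))
    if rise > 0:
        rising = (t >= t0) & (t < t0 + rise)
        y[rising] = peak * (t[rising] - t0) / rise
    falling = t >= t0 + rise
    y[falling] = peak * np.exp(-(t[falling] - t0 - rise) / tau)
    return y


def gen_fscv(
    params: FscvSimParams, seed: int = 0
) -> tuple[FscvTrace, SyntheticGroundTruth]:
    """Simulate an evoked dopamine concentration-vs-time trace (µM).

    Each stimulation pulse contributes one kernel; a 5-pulse 100 Hz train
    sums five kernels 10 ms apart.  After the peak the noiseless trace
    decays as baseline + peak * exp(-(t - t_peak) / τ).
    """
    rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    pulse_times = [
        params.stim_time_s + i * params.pulse_interval_s
        for i in range(params.n_pulses)
    ]
    y = np.full(n, params.baseline_um)
    for t0 in pulse_times:
        y += _fscv_kernel(
            t, t0, params.peak_um, params.rise_time_s, params.decay_tau_s
        )
    if params.noise_sd_um > 0:
        y = y + params.noise_sd_um * rng.standard_normal(n)

    trace = FscvTrace(
        time_s=t,
        value=y,
        units=CONC_UM,
        sample_rate_hz=fs,
        stim_time_s=params.stim_time_s,
    )
    truth = SyntheticGroundTruth(
        event_times_s=np.array(pulse_times),
        event_amps=np.full(len(pulse_times), params.peak_um),
        params_echo=asdict(params),
        seed=seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Operant sessions


def _trial_plan(schedule: ScheduleSpec) -> list[tuple[float, float, float]]:
    """(start_s, end_s, dose) per trial."""
    if schedule.kind == "MULTIDOSE":
        plan = []
        t = 0.0
        for dose in schedule.dose_sequence:
            end = min(t + schedule.trial_s, schedule.session_s)
            plan.append((t, end, float(dose)))
            t = end + schedule.intertrial_s
            if t >= schedule.session_s:
                break
        return plan
    return [(0.0, schedule.session_s, schedule.unit_dose_mg_kg)]


def gen_session(
    agent: AgentParams, schedule: ScheduleSpec, seed: int = 0
) -> OperantEventLog:
    """Simulate one self-administration session as an event log.

    Schedule semantics enforced exactly: each reinforced active poke starts
    an infusion (pump duration scaled to dose), a 5 s cue and a 10 s timeout
    that both begin at the poke; pokes during the timeout are recorded but
    have no consequence; the session ends early at the reinforcer cap; PR
    requirements escalate along the requirement series; multidose trials
    run back-to-back separated by an intertrial timeout during which pokes
    are recorded but never reinforced.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[float, str, float, int]] = []
    n_infusions = 0
    quit_session = False
    session_end = schedule.session_s

    # independent inactive-poke stream over the whole session
    if agent.inactive_rate_hz > 0:
        tt = rng.exponential(1.0 / agent.inactive_rate_hz)
        while tt < session_end:
            rows.append((tt, "INACTIVE_POKE", math.nan, -1))
            tt += rng.exponential(1.0 / agent.inactive_rate_hz)

    capped_at: Optional[float] = None
    for trial_id, (t_start, t_end, dose) in enumerate(_trial_plan(schedule)):
        if quit_session or capped_at is not None:
            break
        rows.append((t_start, "TRIAL_START", dose, trial_id))
        rate = agent.active_rate(dose)
        det = agent.deterministic_interval_s
        if det is None and rate <= 0:
            continue

        timeout_until = -math.inf
        counted = 0
        req = pr_requirement(n_infusions + 1, schedule.pr_a, schedule.pr_b)
        t_next = t_start + (det if det is not None else rng.exponential(1.0 / rate))
        while t_next < t_end:
            t_poke = t_next
            rows.append((t_poke, "ACTIVE_POKE", math.nan, trial_id))
            reinforced = False
            if t_poke >= timeout_until:
                if schedule.kind == "PR":
                    counted += 1
                    if (
                        agent.quit_hazard_per_required_poke > 0
                        and rng.random() < agent.quit_hazard_per_required_poke
                    ):
                        quit_session = True
                    if counted >= req:
                        reinforced = True
                        counted = 0
                else:
                    reinforced = True
            pause = 0.0
            if reinforced:
                n_infusions += 1
                dur = infusion_duration(dose)
                rows.append((t_poke, "INFUSION_START", dose, trial_id))
                rows.append((t_poke + dur, "INFUSION_END", dose, trial_id))
                rows.append((t_poke, "CUE_ON", math.nan, trial_id))
                rows.append((t_poke + schedule.cue_s, "CUE_OFF", math.nan, trial_id))
                rows.append((t_poke, "TIMEOUT_START", math.nan, trial_id))
                rows.append(
                    (t_poke + schedule.timeout_s, "TIMEOUT_END", math.nan, trial_id)
                )
                timeout_until = t_poke + schedule.timeout_s
                req = pr_requirement(
                    n_infusions + 1, schedule.pr_a, schedule.pr_b
                )
                if det is None:
                    pause = agent.post_infusion_pause_s * dose
                if schedule.cap is not None and n_infusions >= schedule.cap:
                    capped_at = t_poke
                    break
            if quit_session:
                break
            gap = det if det is not None else rng.exponential(1.0 / rate)
            t_next = t_poke + pause + gap

    if capped_at is not None:
        session_end = capped_at
        # drop inactive pokes after the early session end
        rows = [
            r
            for r in rows
            if r[0] <= capped_at or r[1] in ("INFUSION_END", "CUE_OFF", "TIMEOUT_END")
        ]

    df = pd.DataFrame(rows, columns=["time_s", "event", "dose_mg_kg", "trial_id"])
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    return OperantEventLog(events=df, schedule=schedule)
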