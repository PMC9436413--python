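"""Operant self-administration schedule analytics.

Implements the schedule mathematics used in intravenous cocaine (and oral
sucrose) self-administration experiments in mice: the progressive-ratio (PR)
response-requirement series and breakpoint, FR1 and multiple-dose session
accounting, acquisition and stability filters, infusion-duration dose scaling,
and dose-response curve construction from event logs.

An :class:`OperantEventLog` is a timestamped record of everything that
happened in a session -- nose pokes on the active and inactive operanda,
infusions, cue-light and timeout intervals, trial boundaries -- together with
the :class:`ScheduleSpec` the session ran under.  All analytics consume this
representation, whether the log came from a real rig export or from the
simulator in :mod:`dopakit.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "ScheduleSpec",
    "OperantEventLog",
    "SessionSummary",
    "AcquisitionCriteria",
    "AcquisitionResult",
    "MultidoseStability",
    "StabilityResult",
    "DoseResponse",
    "IntervalStats",
    "COCAINE_FR1_CRITERIA",
    "SUCROSE_FR1_CRITERIA",
    "pr_requirement",
    "pr_series",
    "breakpoint_from_log",
    "summarize_session",
    "acquisition_filter",
    "infusion_duration",
    "dose_response",
    "multidose_stable",
    "interval_stats",
    "validate_log",
]

EVENT_TYPES = (
    "ACTIVE_POKE",
    "INACTIVE_POKE",
    "INFUSION_START",
    "INFUSION_END",
    "CUE_ON",
    "CUE_OFF",
    "TIMEOUT_START",
    "TIMEOUT_END",
    "TRIAL_START",
)

#: Descending dose sequence of the multiple-dose paradigm, mg/kg/infusion.
#: The session opens with a 30 min trial at the 0.5 mg/kg training dose and
#: then presents six further 30 min trials in descending order.
MULTIDOSE_SEQUENCE = (0.5, 1.0, 0.25, 0.125, 0.0625, 0.03125, 0.0)


class ScheduleError(ValueError):
    """Raised for schedule-specification or schedule-semantics violations."""


@dataclass(frozen=True)
class ScheduleSpec:
    """Parameters of a reinforcement schedule.

    kind
        ``"FR1"`` (fixed ratio 1), ``"MULTIDOSE"`` (descending-dose FR1
        trials in one session) or ``"PR"`` (progressive ratio).
    unit_dose_mg_kg
        Unit dose per infusion for FR1/PR sessions.
    dose_sequence
        Ordered doses (mg/kg/infusion) for MULTIDOSE sessions.
    session_s
        Session duration in seconds (10800 for 3 hr cocaine sessions,
        3600 for 1 hr sucrose sessions).
    timeout_s / cue_s
        Post-reinforcement timeout and cue-light durations; both start at
        the reinforced poke and run concurrently.
    cap
        Maximum reinforcers per session (sessions end early at the cap);
        ``None`` disables the cap (default for MULTIDOSE).
    trial_s / intertrial_s
        MULTIDOSE per-trial duration and the intertrial timeout between
        dose trials.
    pr_a, pr_b
        Coefficients of the PR requirement formula
        ``round(a * (exp(b * n) - 1))``.
    """

    kind: str = "FR1"
    unit_dose_mg_kg: float = 0.5
    dose_sequence: Sequence[float] = ()
    session_s: float = 10800.0
    timeout_s: float = 10.0
    cue_s: float = 5.0
    cap: Optional[int] = 64
    trial_s: float = 1800.0
    intertrial_s: float = 60.0
    pr_a: float = 5.0
    pr_b: float = 0.18

    def __post_init__(self) -> None:
        if self.kind not in ("FR1", "MULTIDOSE", "PR"):
            raise ScheduleError(f"unknown schedule kind: {self.kind!r}")
        if self.cap is not None and self.cap < 1:
            raise ScheduleError("cap must be >= 1 (or None)")
        if self.timeout_s < 0:
            raise ScheduleError("timeout_s must be >= 0")
        if self.session_s <= 0:
            raise ScheduleError("session_s must be positive")
        if self.kind == "MULTIDOSE" and len(self.dose_sequence) == 0:
            raise ScheduleError("MULTIDOSE schedule requires a dose_sequence")

    @classmethod
    def fr1_cocaine(cls, unit_dose_mg_kg: float = 0.5) -> "ScheduleSpec":
        return cls(kind="FR1", unit_dose_mg_kg=unit_dose_mg_kg)

    @classmethod
    def fr1_sucrose(cls) -> "ScheduleSpec":
        # 1 hr sessions; "dose" carries no mg/kg meaning for sucrose.
        return cls(kind="FR1", unit_dose_mg_kg=0.0, session_s=3600.0)

    @classmethod
    def pr_cocaine(cls, unit_dose_mg_kg: float = 0.5) -> "ScheduleSpec":
        return cls(kind="PR", unit_dose_mg_kg=unit_dose_mg_kg)

    @classmethod
    def multidose_cocaine(cls) -> "ScheduleSpec":
        return cls(
            kind="MULTIDOSE",
            dose_sequence=MULTIDOSE_SEQUENCE,
            cap=None,
            session_s=7 * 1800.0 + 6 * 60.0,
        )


LOG_COLUMNS = ("time_s", "event", "dose_mg_kg", "trial_id")


@dataclass
class OperantEventLog:
    """Timestamped behavioral events plus schedule metadata.

    ``events`` is a DataFrame with columns ``time_s`` (seconds from session
    start, nondecreasing), ``event`` (one of :data:`EVENT_TYPES`),
    ``dose_mg_kg`` (NaN except on dose-bearing rows) and ``trial_id``
    (0-based trial index).
    """

    events: pd.DataFrame
    schedule: ScheduleSpec

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.events.columns]
        if missing:
            raise ScheduleError(f"event log missing columns: {missing}")
        t = self.events["time_s"].to_numpy(dtype=float)
        if len(t) > 1:
            bad = np.flatnonzero(np.diff(t) < 0)
            if bad.size:
                raise ScheduleError(
                    f"event times decrease at row {int(bad[0]) + 1}"
                )
        bad_ev = set(self.events["event"]) - set(EVENT_TYPES)
        if bad_ev:
            raise ScheduleError(f"unknown event types: {sorted(bad_ev)}")
        inf = self.events[self.events["event"] == "INFUSION_START"]
        if inf["dose_mg_kg"].isna().any():
            row = int(inf.index[inf["dose_mg_kg"].isna()][0])
            raise ScheduleError(f"INFUSION_START without dose at row {row}")

    def of_type(self, event: str) -> pd.DataFrame:
        return self.events[self.events["event"] == event]

    @property
    def infusion_times(self) -> np.ndarray:
        return self.of_type("INFUSION_START")["time_s"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SessionSummary:
    """Per-session counts: pokes, infusions and drug intake."""

    active_pokes: int
    inactive_pokes: int
    infusions: int
    intake_mg_kg: float
    per_dose: Mapping[float, tuple[int, float]] = field(default_factory=dict)
    breakpoint: Optional[int] = None

    @property
    def active_inactive_ratio(self) -> float:
        """Active/inactive poke ratio; +inf when inactive is 0 and active > 0."""
        if self.inactive_pokes == 0:
            return math.inf if self.active_pokes > 0 else 0.0
        return self.active_pokes / self.inactive_pokes


# ---------------------------------------------------------------------------
# Progressive ratio


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def pr_requirement(n: int, a: float = 5.0, b: float = 0.18) -> int:
    """Response requirement for the n-th infusion on the PR schedule.

    ``round(a * (exp(b * n) - 1))`` with half-away-from-zero rounding,
    floored at 1.  With the default coefficients (a=5, b=0.18) this yields
    the series 1, 2, 4, 5, 7, 10, 13, 16, 20, 25, 31, 38, 47, 57, 69, 84,
    102, ... for n = 1, 2, 3, ...

    Note the series as conventionally printed opens with a duplicated "1"
    (1, 1, 2, 4, ...); the formula itself produces a single leading 1
    (5*(e^0.18 - 1) = 0.986 rounds to 1).  This function follows the
    formula; see :func:`pr_series` for the printed-series variant.
    """
    if n < 1:
        raise ValueError(f"infusion index must be >= 1, got {n}")
    return max(1, _round_half_away(a * (math.exp(b * n) - 1.0)))


def pr_series(
    length: int,
    a: float = 5.0,
    b: float = 0.18,
    leading_free_reinforcer: bool = False,
) -> list[int]:
    """Requirement series ``[pr_requirement(1), ..., pr_requirement(length)]``.

    ``leading_free_reinforcer=True`` prepends the extra requirement-1 entry
    of the conventionally printed series (reading the duplicated leading
    "1, 1" as a free/priming first reinforcer); the returned list then has
    ``length + 1`` entries.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    series = [pr_requirement(n, a, b) for n in range(1, length + 1)]
    if leading_free_reinforcer:
        series = [1] + series
    return series


def breakpoint_from_log(log: OperantEventLog, gap_s: float = 3600.0) -> int:
    """PR breakpoint: requirement completed for the last infusion obtained
    before the first infusion-free period of at least ``gap_s`` seconds.

    The scan includes the interval from session start to the first infusion
    and the terminal interval to session end.  A terminal infusion-free
    interval shorter than ``gap_s`` does not truncate: the last infusion's
    requirement stands.  A session with no infusions has breakpoint 0.
    """
    if log.schedule.kind != "PR":
        raise ScheduleError(
            f"breakpoint requires a PR log, got {log.schedule.kind}"
        )
    times = log.infusion_times
    if times.size == 0:
        return 0
    a, b = log.schedule.pr_a, log.schedule.pr_b
    bounds = np.concatenate([[0.0], times, [max(log.schedule.session_s, times[-1])]])
    gaps = np.diff(bounds)  # gaps[k] precedes infusion k (k = 0..n-1); gaps[n] is terminal
    for k in range(len(times) + 1):
        if gaps[k] >= gap_s:
            # k infusions occurred before this gap
            return pr_requirement(k, a, b) if k >= 1 else 0
    return pr_requirement(len(times), a, b)


# ---------------------------------------------------------------------------
# Session accounting


def summarize_session(log: OperantEventLog) -> SessionSummary:
    """Count pokes and infusions and total the drug intake.

    Pokes during timeouts are included in the counts (they are recorded but
    have no scheduled consequence).  Intake is the dose-weighted infusion
    sum, decomposed per dose in ``per_dose``.
    """
    ev = log.events
    active = int((ev["event"] == "ACTIVE_POKE").sum())
    inactive = int((ev["event"] == "INACTIVE_POKE").sum())
    inf = ev[ev["event"] == "INFUSION_START"]
    per_dose: dict[float, tuple[int, float]] = {}
    for dose, grp in inf.groupby("dose_mg_kg"):
        d = float(dose)
        per_dose[d] = (len(grp), len(grp) * d)
    intake = float(sum(v[1] for v in per_dose.values()))
    bp = None
    if log.schedule.kind == "PR":
        bp = breakpoint_from_log(log)
    return SessionSummary(
        active_pokes=active,
        inactive_pokes=inactive,
        infusions=int(len(inf)),
        intake_mg_kg=intake,
        per_dose=per_dose,
        breakpoint=bp,
    )


# ---------------------------------------------------------------------------
# Acquisition / stability criteria


@dataclass(frozen=True)
class AcquisitionCriteria:
    """Per-animal filter defining stable self-administration.

    Cocaine FR1: >=25 infusions and >2:1 active/inactive ratio for 3
    consecutive days, with <20% variability in daily infusions across two
    consecutive sessions.  The sucrose variant requires >=30 rewards over 4
    consecutive days including the last training day.  Animals not reaching
    criteria within ``max_sessions`` days are excluded.
    """

    min_infusions: int = 25
    ratio_threshold: float = 2.0
    consecutive_days: int = 3
    variability_threshold: float = 0.20
    max_sessions: int = 10
    require_last_day: bool = False

    def __post_init__(self) -> None:
        if (
            self.min_infusions <= 0
            or self.ratio_threshold <= 0
            or self.consecutive_days <= 0
            or self.variability_threshold <= 0
        ):
            raise ValueError("criteria thresholds must be positive")


COCAINE_FR1_CRITERIA = AcquisitionCriteria()
SUCROSE_FR1_CRITERIA = AcquisitionCriteria(
    min_infusions=30, consecutive_days=4, require_last_day=True
)


@dataclass
class AcquisitionResult:
    acquired: bool
    acquisition_day: Optional[int]  # 1-based
    exclusion_reason: Optional[str]


def _pairwise_variation(a: float, b: float) -> float:
    m = (a + b) / 2.0
    if m == 0:
        return 0.0 if a == b else math.inf
    return abs(a - b) / m


def acquisition_filter(
    summaries: Sequence[SessionSummary],
    criteria: AcquisitionCriteria = COCAINE_FR1_CRITERIA,
) -> AcquisitionResult:
    """Apply the acquisition criteria to a subject's daily session summaries.

    A subject acquires on the first day ``d`` such that the
    ``consecutive_days`` window ending at ``d`` has every day meeting the
    infusion minimum and the active/inactive ratio, and the last two days of
    the window differ in infusion count by at most the variability threshold
    (|a-b| / mean(a, b)).  With ``require_last_day`` the qualifying window
    must end on the final training day.  A zero inactive count with active
    responding passes the ratio test (ratio treated as +inf).
    """
    if len(summaries) == 0:
        raise ValueError("need at least one daily summary")
    days = summaries[: criteria.max_sessions]
    n = len(days)
    k = criteria.consecutive_days

    def day_ok(s: SessionSummary) -> bool:
        return (
            s.infusions >= criteria.min_infusions
            and s.active_inactive_ratio > criteria.ratio_threshold
        )

    candidates = range(k - 1, n) if not criteria.require_last_day else [n - 1]
    for d in candidates:
        if d < k - 1:
            continue
        window = days[d - k + 1 : d + 1]
        if not all(day_ok(s) for s in window):
            continue
        var = _pairwise_variation(window[-1].infusions, window[-2].infusions)
        if var <= criteria.variability_threshold:
            return AcquisitionResult(True, d + 1, None)

    if not any(s.infusions >= criteria.min_infusions for s in days):
        reason = "min_infusions"
    elif not any(day_ok(s) for s in days):
        reason = "ratio"
    else:
        reason = "stability"
    return AcquisitionResult(False, None, reason)


# ---------------------------------------------------------------------------
# Dose scaling and dose-response


def infusion_duration(
    dose_mg_kg: float, anchor: tuple[float, float] = (1.0, 7.07)
) -> float:
    """Pump duration (s) for a unit dose, proportional to dose.

    Anchored at 1.0 mg/kg <-> 7.07 s, reproducing the multiple-dose
    durations 7.07, 1.77, 0.88, 0.44, 0.22 and 0 s for 1.0, 0.25, 0.125,
    0.0625, 0.03125 and 0.0 mg/kg (reported to 2 decimals, half away from
    zero).
    """
    if dose_mg_kg < 0:
        raise ValueError("dose must be >= 0")
    anchor_dose, anchor_s = anchor
    raw = anchor_s * dose_mg_kg / anchor_dose
    return _round_half_away(raw * 100.0) / 100.0


@dataclass
class DoseResponse:
    """Per-dose infusion and intake curves from a multidose session."""

    doses: list[float]  # in trial order
    infusions: list[int]
    intake_mg_kg: list[float]
    peak_dose: Optional[float]  # dose with maximal infusions; None if all zero

    @property
    def total_infusions(self) -> int:
        return int(sum(self.infusions))

    @property
    def total_intake_mg_kg(self) -> float:
        return float(sum(self.intake_mg_kg))


def dose_response(log: OperantEventLog) -> DoseResponse:
    """Build the per-trial dose-response curve from a MULTIDOSE event log.

    Each trial (marked by TRIAL_START) contributes one point: the dose it
    presented, the infusions earned and the resulting intake.  The dose
    maintaining maximal responding is reported (``None``, flagged, when no
    infusions were earned at any dose).
    """
    if log.schedule.kind != "MULTIDOSE":
        raise ScheduleError("dose_response requires a MULTIDOSE log")
    trials = log.of_type("TRIAL_START")
    if len(trials) == 0:
        raise ScheduleError("multidose log has no TRIAL_START markers")
    inf = log.of_type("INFUSION_START")
    doses, counts, intake = [], [], []
    for _, row in trials.iterrows():
        tid = int(row["trial_id"])
        dose = float(row["dose_mg_kg"])
        n = int((inf["trial_id"] == tid).sum())
        doses.append(dose)
        counts.append(n)
        intake.append(n * dose)
    peak = None
    if any(c > 0 for c in counts):
        peak = doses[int(np.argmax(counts))]
    return DoseResponse(doses, counts, intake, peak)


@dataclass(frozen=True)
class MultidoseStability:
    """Stability rules for consecutive multidose test sessions."""

    infusion_variation_threshold: float = 0.20
    max_dose_drift_log10: float = 0.5

    def __post_init__(self) -> None:
        if (
            self.infusion_variation_threshold <= 0
            or self.max_dose_drift_log10 <= 0
        ):
            raise ValueError("stability thresholds must be positive")


@dataclass
class StabilityResult:
    stable: bool
    infusion_variation: float
    dose_drift_log10: Optional[float]
    undefined: bool = False


def multidose_stable(
    first: DoseResponse,
    second: DoseResponse,
    rules: MultidoseStability = MultidoseStability(),
) -> StabilityResult:
    """Check two consecutive multidose sessions for stable responding.

    Stable iff (1) total infusions vary by <= 20% (|n1-n2| / mean) and
    (2) the dose maintaining maximal responding drifts by no more than half
    a log10 unit.  Two sessions with no infusions at all are flagged
    undefined.
    """
    n1, n2 = first.total_infusions, second.total_infusions
    if n1 == 0 and n2 == 0:
        return StabilityResult(False, 0.0, None, undefined=True)
    variation = _pairwise_variation(n1, n2)
    drift: Optional[float] = None
    dose_ok = False
    if first.peak_dose and second.peak_dose:
        drift = abs(math.log10(first.peak_dose) - math.log10(second.peak_dose))
        dose_ok = drift <= rules.max_dose_drift_log10
    stable = variation <= rules.infusion_variation_threshold and dose_ok
    return StabilityResult(stable, variation, drift)


# ---------------------------------------------------------------------------
# Inter-infusion intervals


@dataclass
class IntervalStats:
    """Inter-infusion interval summary; quantifies regular vs sporadic intake."""

    intervals_s: np.ndarray
    mean_s: float
    cv: float
    gaps_s: np.ndarray  # intervals exceeding the gap threshold
    defined: bool = True


def interval_stats(
    log: OperantEventLog, gap_threshold_s: float = 600.0
) -> IntervalStats:
    """Summarize intervals between consecutive infusions.

    CV = population SD / mean of the intervals.  With fewer than 2 infusions
    the result is flagged undefined and carries empty arrays.
    """
    times = log.infusion_times
    if times.size < 2:
        return IntervalStats(
            intervals_s=np.array([]),
            mean_s=math.nan,
            cv=math.nan,
            gaps_s=np.array([]),
            defined=False,
        )
    iv = np.diff(times)
    mean = float(iv.mean())
    cv = float(iv.std() / mean) if mean > 0 else math.nan
    return IntervalStats(iv, mean, cv, iv[iv > gap_threshold_s])


# ---------------------------------------------------------------------------
# Schedule-legality validation (replay soundness)


def validate_log(log: OperantEventLog) -> None:
    """Validate schedule legality of an event log; raises ScheduleError.

    Checks: no two infusions closer than the timeout; the reinforcer count
    never exceeds the cap; for PR logs, the number of counted (non-timeout)
    active pokes between successive infusions equals the requirement series.
    """
    sched = log.schedule
    times = log.infusion_times
    if times.size > 1:
        gaps = np.diff(times)
        if (gaps < sched.timeout_s - 1e-9).any():
            raise ScheduleError("infusions closer than the timeout")
    if sched.cap is not None and times.size > sched.cap:
        raise ScheduleError(
            f"{times.size} infusions exceed the cap of {sched.cap}"
        )
    if sched.kind == "PR":
        _validate_pr_requirements(log)


def _validate_pr_requirements(log: OperantEventLog) -> None:
    ev = log.events
    pokes = ev[ev["event"] == "ACTIVE_POKE"]["time_s"].to_numpy(dtype=float)
    times = log.infusion_times
    prev_timeout_end = -math.inf
    counted = 0
    k = 0
    required = pr_requirement(1, log.schedule.pr_a, log.schedule.pr_b)
    for t_inf in times:
        # counted pokes: active pokes in (prev_timeout_end, t_inf] outside timeout
        in_window = pokes[(pokes > prev_timeout_end) & (pokes <= t_inf)]
        counted = len(in_window)
        if counted != required:
            raise ScheduleError(
                f"infusion {k + 1}: {counted} counted pokes, "
                f"requirement was {required}"
            )
        k += 1
        required = pr_requirement(k + 1, log.schedule.pr_a, log.schedule.pr_b)
        prev_timeout_end = t_inf + log.schedule.timeout_s
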