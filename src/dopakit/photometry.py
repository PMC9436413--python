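"""Dual-channel fiber-photometry analysis.

Converts two-channel recordings -- a dopamine-sensitive sensor channel
(GRAB-DA class sensor excited at 465 nm) and a dopamine-independent control
channel (mCherry excited at 560 nm) -- into ΔF/F, detects dopamine
transients with a rolling z-score threshold, and compares transient
frequencies across recording epochs.

The ΔF/F construction regresses the sensor channel on the control channel
(ordinary least squares, per duty-cycle block), subtracts the fitted control
from the sensor signal and divides by the fitted control:

    ΔF/F = (F465 - fit560) / fit560,   fit560 = slope * F560 + intercept.

Shared artifacts (photobleaching, motion) appear in both channels and are
removed by the fit; dopamine transients are sensor-specific and survive.

Transient onsets are samples whose z score exceeds the mean plus k times the
standard deviation of the z scores in the immediately preceding window
(default 0.5 s, k = 3), evaluated within a duty-cycle block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "PhotometryTrace",
    "ControlFit",
    "DffTrace",
    "ZScoredTrace",
    "DetectionParams",
    "TransientEvent",
    "EpochSpec",
    "EpochComparison",
    "split_blocks",
    "fit_control",
    "compute_dff",
    "zscore",
    "detect_transients",
    "transient_frequency",
    "epoch_compare",
    "match_events",
    "lowpass",
]


class PhotometryError(ValueError):
    pass


@dataclass
class PhotometryTrace:
    """Time-aligned sensor (465 nm) / control (560 nm) sample pairs.

    ``mask`` marks recorded samples; samples during duty-cycle off periods
    are masked out (their channel values may be NaN).
    """

    time_s: np.ndarray
    f465: np.ndarray
    f560: np.ndarray
    mask: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f560 = np.asarray(self.f560, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.time_s)
        if not (len(self.f465) == len(self.f560) == len(self.mask) == n):
            raise PhotometryError("per-sample fields have unequal lengths")
        if n > 1 and not (np.diff(self.time_s) > 0).all():
            raise PhotometryError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class ControlFit:
    """Affine fit of the sensor channel on the control channel (one block)."""

    slope: float
    intercept: float
    segment_id: int
    r2: float


@dataclass
class DffTrace:
    """ΔF/F trace; values are NaN where the recording mask is off."""

    time_s: np.ndarray
    dff: np.ndarray
    mask: np.ndarray
    sample_rate_hz: float
    fits: list[ControlFit] = field(default_factory=list)
    blocks: list[slice] = field(default_factory=list)


@dataclass
class ZScoredTrace:
    """Z-scored ΔF/F; reference population is per block or global."""

    time_s: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    sample_rate_hz: float
    blocks: list[slice] = field(default_factory=list)
    reference: str = "PER_BLOCK"


@dataclass(frozen=True)
class DetectionParams:
    """Rolling-threshold transient detection parameters.

    window_s
        Length of the prior reference window (s).
    k
        Threshold multiplier: onset iff z > window mean + k * window SD.
    refractory_s
        Minimum spacing between emitted onsets.
    z_reference
        Population for the z transform: per duty-cycle block (default) or
        the whole masked trace.
    """

    window_s: float = 0.5
    k: float = 3.0
    refractory_s: float = 0.5
    z_reference: Literal["PER_BLOCK", "GLOBAL"] = "PER_BLOCK"

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.k <= 0 or self.refractory_s < 0:
            raise PhotometryError("invalid detection parameters")


@dataclass
class TransientEvent:
    """A detected dopamine transient."""

    onset_time_s: float
    peak_time_s: float
    peak_z: float
    block_id: int


@dataclass(frozen=True)
class EpochSpec:
    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise PhotometryError("epoch must have start_s < end_s")


@dataclass
class EpochComparison:
    rate_pre: float
    rate_post: float
    ratio: float
    undefined: bool = False


# ---------------------------------------------------------------------------


def split_blocks(trace: PhotometryTrace) -> list[slice]:
    """Contiguous masked-on runs of the trace, as slices into its arrays."""
    m = trace.mask
    if not m.any():
        raise PhotometryError("mask is all-off; no recorded samples")
    padded = np.concatenate([[False], m, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def fit_control(
    f465: np.ndarray, f560: np.ndarray, segment_id: int = 0
) -> ControlFit:
    """OLS of the sensor channel on the control channel over one segment."""
    f465 = np.asarray(f465, dtype=float)
    f560 = np.asarray(f560, dtype=float)
    if len(f465) < 10:
        raise PhotometryError(
            f"segment {segment_id}: need >= 10 samples, got {len(f465)}"
        )
    if np.ptp(f560) == 0:
        raise PhotometryError(
            f"segment {segment_id}: control channel has zero variance"
        )
    res = _stats.linregress(f560, f465)
    return ControlFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        segment_id=segment_id,
        r2=float(res.rvalue**2),
    )


def compute_dff(trace: PhotometryTrace, per_block: bool = True) -> DffTrace:
    """ΔF/F = (F465 - fitted F560) / fitted F560.

    The control fit is computed independently per duty-cycle block by
    default (photobleaching state differs across blocks); ``per_block=False``
    fits the whole masked trace with one line.
    """
    blocks = split_blocks(trace)
    dff = np.full(len(trace), np.nan)
    fits: list[ControlFit] = []
    if per_block:
        groups = [(i, blk, [blk]) for i, blk in enumerate(blocks)]
    else:
        groups = [(0, None, blocks)]
    for seg_id, _, members in groups:
        f465 = np.concatenate([trace.f465[b] for b in members])
        f560 = np.concatenate([trace.f560[b] for b in members])
        fit = fit_control(f465, f560, segment_id=seg_id)
        fits.append(fit)
        for b in members:
            fitted = fit.slope * trace.f560[b] + fit.intercept
            bad = np.flatnonzero(fitted <= 0)
            if bad.size:
                idx = b.start + int(bad[0])
                raise PhotometryError(
                    f"fitted control signal <= 0 at sample {idx}"
                )
            dff[b] = (trace.f465[b] - fitted) / fitted
    return DffTrace(
        time_s=trace.time_s,
        dff=dff,
        mask=trace.mask,
        sample_rate_hz=trace.sample_rate_hz,
        fits=fits,
        blocks=blocks,
    )


def zscore(
    dff: DffTrace, reference: Literal["PER_BLOCK", "GLOBAL"] = "PER_BLOCK"
) -> ZScoredTrace:
    """Z transform of ΔF/F: z = (dff - mean_ref) / sd_ref.

    The reference population is each duty-cycle block (``PER_BLOCK``) or all
    masked samples (``GLOBAL``).  Population SD (ddof=0).
    """
    z = np.full_like(dff.dff, np.nan)
    if reference == "GLOBAL":
        pops = [np.concatenate([dff.dff[b] for b in dff.blocks])]
        targets = [dff.blocks]
    elif reference == "PER_BLOCK":
        pops = [dff.dff[b] for b in dff.blocks]
        targets = [[b] for b in dff.blocks]
    else:
        raise PhotometryError(f"unknown z reference: {reference!r}")
    for pop, blks in zip(pops, targets):
        if len(pop) < 2:
            raise PhotometryError("z reference population needs >= 2 samples")
        mu, sd = float(np.mean(pop)), float(np.std(pop))
        if sd == 0:
            raise PhotometryError("zero-variance z reference population")
        for b in blks:
            z[b] = (dff.dff[b] - mu) / sd
    return ZScoredTrace(
        time_s=dff.time_s,
        z=z,
        mask=dff.mask,
        sample_rate_hz=dff.sample_rate_hz,
        blocks=list(dff.blocks),
        reference=reference,
    )


def detect_transients(
    ztrace: ZScoredTrace, params: DetectionParams = DetectionParams()
) -> list[TransientEvent]:
    """Detect transient onsets with the rolling prior-window threshold.

    A sample i is an onset iff z[i] > mean + k * SD of the z scores over the
    preceding ``window_s`` seconds, where the prior window lies entirely
    within the same duty-cycle block, and no onset was emitted within
    ``refractory_s``.  The event peak is the z maximum between the onset and
    the first return below the onset's window mean (or block end).
    """
    fs = ztrace.sample_rate_hz
    w = int(round(params.window_s * fs))
    if w < 2:
        raise PhotometryError(
            "window_s * sample_rate must cover at least 2 samples"
        )
    if all((b.stop - b.start) <= w for b in ztrace.blocks):
        raise PhotometryError("window longer than every block")
    refr = params.refractory_s
    events: list[TransientEvent] = []
    last_onset_t = -math.inf
    for block_id, b in enumerate(ztrace.blocks):
        z = ztrace.z[b]
        t = ztrace.time_s[b]
        n = len(z)
        if n <= w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(z, w)
        mu = windows.mean(axis=1)  # mu[j] over z[j:j+w]
        sd = windows.std(axis=1)
        # candidate onset at i (i >= w): z[i] > mu[i-w] + k * sd[i-w]
        thr = mu[: n - w] + params.k * sd[: n - w]
        cand = np.flatnonzero(z[w:] > thr) + w
        for i in cand:
            if t[i] - last_onset_t < refr:
                continue
            onset_mu = mu[i - w]
            below = np.flatnonzero(z[i:] < onset_mu)
            end = i + int(below[0]) if below.size else n
            peak_rel = int(np.argmax(z[i:end])) if end > i else 0
            events.append(
                TransientEvent(
                    onset_time_s=float(t[i]),
                    peak_time_s=float(t[i + peak_rel]),
                    peak_z=float(z[i + peak_rel]),
                    block_id=block_id,
                )
            )
            last_onset_t = float(t[i])
    return events


def transient_frequency(
    events: Sequence[TransientEvent],
    epoch: EpochSpec,
    trace: ZScoredTrace,
) -> float:
    """Transient rate in events/min over an epoch.

    The denominator is the masked-on (recorded) time within the epoch, so
    duty-cycle off periods do not dilute the rate.
    """
    in_epoch = (trace.time_s >= epoch.start_s) & (trace.time_s < epoch.end_s)
    on_minutes = int((trace.mask & in_epoch).sum()) / trace.sample_rate_hz / 60.0
    if on_minutes == 0:
        raise PhotometryError(
            f"epoch [{epoch.start_s}, {epoch.end_s}) has no recorded time"
        )
    n = sum(1 for e in events if epoch.start_s <= e.onset_time_s < epoch.end_s)
    return n / on_minutes


def epoch_compare(
    events: Sequence[TransientEvent],
    pre: EpochSpec,
    post: EpochSpec,
    trace: ZScoredTrace,
) -> EpochComparison:
    """Paired transient rates (events/min) for two epochs and their ratio.

    The ratio is flagged undefined when the pre-epoch rate is zero.
    """
    if pre.start_s < post.end_s and post.start_s < pre.end_s:
        raise PhotometryError("pre and post epochs overlap")
    rate_pre = transient_frequency(events, pre, trace)
    rate_post = transient_frequency(events, post, trace)
    if rate_pre == 0:
        return EpochComparison(rate_pre, rate_post, math.nan, undefined=True)
    return EpochComparison(rate_pre, rate_post, rate_post / rate_pre)


# ---------------------------------------------------------------------------


def match_events(
    true_times_s: Sequence[float],
    detected_times_s: Sequence[float],
    tol_s: float = 0.5,
) -> tuple[float, float, int]:
    """Greedy one-to-one matching of detections to ground-truth events.

    Returns (recall, precision, n_matched).  Each truth event matches at
    most one detection within ``tol_s``; detections are consumed in time
    order.
    """
    truth = sorted(float(t) for t in true_times_s)
    det = sorted(float(t) for t in detected_times_s)
    matched = 0
    j = 0
    for t in truth:
        while j < len(det) and det[j] < t - tol_s:
            j += 1
        if j < len(det) and abs(det[j] - t) <= tol_s:
            matched += 1
            j += 1
    recall = matched / len(truth) if truth else math.nan
    precision = matched / len(det) if det else math.nan
    return recall, precision, matched


def lowpass(
    x: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 6.0, order: int = 4
) -> np.ndarray:
    """Optional zero-phase Butterworth low-pass for raw synthetic traces."""
    b, a = _signal.butter(order, cutoff_hz / (sample_rate_hz / 2.0))
    return _signal.filtfilt(b, a, np.asarray(x, dtype=float))
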