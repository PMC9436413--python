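"""CSV/JSON dialects and run configuration.

All desk-scale data move through plain-text formats:

* photometry traces -- CSV with columns ``time_s, f465, f560, mask``
* FSCV traces -- CSV with columns ``time_s, value, units, stim_time_s``
* calibration standards -- CSV with columns ``concentration_um, current_na``
* operant event logs -- CSV with columns ``time_s, event, dose_mg_kg,
  trial_id`` preceded by a single ``#schedule=<json>`` header line carrying
  the schedule metadata
* analysis summaries and ground truth -- JSON

Every writer's output round-trips through the matching reader (values to
1e-12, metadata exactly).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd
import yaml

from .behavior import OperantEventLog, ScheduleSpec
from .fscv import Calibration, CalibrationStandard, FscvTrace
from .photometry import PhotometryTrace
from .simulate import SyntheticGroundTruth

__all__ = [
    "IoError",
    "read_photometry_csv",
    "write_photometry_csv",
    "read_fscv_csv",
    "write_fscv_csv",
    "read_standards_csv",
    "write_standards_csv",
    "read_event_log_csv",
    "write_event_log_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_json",
    "RunConfig",
    "load_config",
]

PathLike = Union[str, Path]


class IoError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise IoError(f"{path}: missing columns {missing}")


def _check_monotone(t: np.ndarray, path: PathLike, strict: bool = True) -> None:
    d = np.diff(t)
    bad = np.flatnonzero(d <= 0 if strict else d < 0)
    if bad.size:
        raise IoError(
            f"{path}: time_s not {'strictly increasing' if strict else 'nondecreasing'}"
            f" at data row {int(bad[0]) + 2}"
        )


# ---------------------------------------------------------------------------
# Photometry traces


def write_photometry_csv(trace: PhotometryTrace, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "f465": trace.f465,
            "f560": trace.f560,
            "mask": trace.mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_photometry_csv(path: PathLike) -> PhotometryTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "f465", "f560", "mask"), path)
    t = df["time_s"].to_numpy(dtype=float)
    _check_monotone(t, path)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else math.nan
    return PhotometryTrace(
        time_s=t,
        f465=df["f465"].to_numpy(dtype=float),
        f560=df["f560"].to_numpy(dtype=float),
        mask=df["mask"].to_numpy().astype(bool),
        sample_rate_hz=fs,
    )


# ---------------------------------------------------------------------------
# FSCV traces and calibration standards


def write_fscv_csv(trace: FscvTrace, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "value": trace.value,
            "units": trace.units,
            "stim_time_s": trace.stim_time_s,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_fscv_csv(path: PathLike) -> FscvTrace:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "value", "units"), path)
    units = df["units"].unique()
    if len(units) != 1:
        raise IoError(f"{path}: mixed units {list(units)}")
    t = df["time_s"].to_numpy(dtype=float)
    _check_monotone(t, path)
    stim = float(df["stim_time_s"].iloc[0]) if "stim_time_s" in df.columns else 0.0
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else math.nan
    return FscvTrace(
        time_s=t,
        value=df["value"].to_numpy(dtype=float),
        units=str(units[0]),
        sample_rate_hz=fs,
        stim_time_s=stim,
    )


def write_standards_csv(
    standards: list[CalibrationStandard], path: PathLike
) -> None:
    pd.DataFrame(
        {
            "concentration_um": [s.concentration_um for s in standards],
            "current_na": [s.current_na for s in standards],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_standards_csv(path: PathLike) -> list[CalibrationStandard]:
    df = pd.read_csv(path)
    _require_columns(df, ("concentration_um", "current_na"), path)
    return [
        CalibrationStandard(float(r.concentration_um), float(r.current_na))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Operant event logs


def write_event_log_csv(log: OperantEventLog, path: PathLike) -> None:
    sched = dataclasses.asdict(log.schedule)
    sched["dose_sequence"] = list(sched["dose_sequence"])
    with open(path, "w") as fh:
        fh.write("#schedule=" + json.dumps(sched) + "\n")
        log.events.to_csv(fh, index=False, float_format="%.17g")


def read_event_log_csv(path: PathLike) -> OperantEventLog:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#schedule="):
            raise IoError(f"{path}: missing '#schedule=' header line")
        sched_dict = json.loads(first[len("#schedule="):])
        sched_dict["dose_sequence"] = tuple(sched_dict.get("dose_sequence", ()))
        schedule = ScheduleSpec(**sched_dict)
        df = pd.read_csv(fh)
    _require_columns(df, ("time_s", "event", "dose_mg_kg", "trial_id"), path)
    _check_monotone(df["time_s"].to_numpy(dtype=float), path, strict=False)
    return OperantEventLog(events=df, schedule=schedule)


# ---------------------------------------------------------------------------
# JSON helpers


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_json(obj: Any, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ground_truth_json(truth: SyntheticGroundTruth, path: PathLike) -> None:
    write_json(
        {
            "event_times_s": truth.event_times_s,
            "event_amps": truth.event_amps,
            "params_echo": truth.params_echo,
            "seed": truth.seed,
        },
        path,
    )


def read_ground_truth_json(path: PathLike) -> SyntheticGroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticGroundTruth(
        event_times_s=np.array(d["event_times_s"], dtype=float),
        event_amps=np.array(d["event_amps"], dtype=float),
        params_echo=d["params_echo"],
        seed=int(d["seed"]),
    )


# ---------------------------------------------------------------------------
# Run configuration


_CONFIG_SECTIONS = ("photometry", "fscv", "session", "detection", "output")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration: per-module parameter overrides plus a seed.

    Section dictionaries hold keyword overrides for the corresponding
    parameter dataclasses; unknown sections or keys are rejected when the
    config is applied.
    """

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    photometry: dict = dataclasses.field(default_factory=dict)
    fscv: dict = dataclasses.field(default_factory=dict)
    session: dict = dataclasses.field(default_factory=dict)
    detection: dict = dataclasses.field(default_factory=dict)


def load_config(path: PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise IoError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
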