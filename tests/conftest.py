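import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dopakit.behavior import OperantEventLog, ScheduleSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_log(
    schedule: ScheduleSpec,
    infusion_times=(),
    doses=None,
    active_pokes=(),
    inactive_pokes=(),
    trial_ids=None,
    trial_starts=None,
) -> OperantEventLog:
    """Construct an event log from explicit event times (test helper)."""
    rows = []
    doses = list(doses) if doses is not None else [
        schedule.unit_dose_mg_kg
    ] * len(infusion_times)
    tids = list(trial_ids) if trial_ids is not None else [0] * len(infusion_times)
    for t, d, tid in zip(infusion_times, doses, tids):
        rows.append((t, "INFUSION_START", d, tid))
        rows.append((t, "TIMEOUT_START", math.nan, tid))
        rows.append((t + schedule.timeout_s, "TIMEOUT_END", math.nan, tid))
    for t in active_pokes:
        rows.append((t, "ACTIVE_POKE", math.nan, 0))
    for t in inactive_pokes:
        rows.append((t, "INACTIVE_POKE", math.nan, 0))
    for tid, (t, d) in enumerate(trial_starts or []):
        rows.append((t, "TRIAL_START", d, tid))
    df = pd.DataFrame(
        rows, columns=["time_s", "event", "dose_mg_kg", "trial_id"]
    ).sort_values("time_s", kind="stable").reset_index(drop=True)
    return OperantEventLog(events=df, schedule=schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
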