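#!/usr/bin/env python
"""Operant schedule analytics: acquisition, breakpoint, dose-response.

Reads the simulated sessions from 01 and additionally simulates a 10-day
FR1 training cohort, then reports: the acquisition-filter decision per
subject, the PR breakpoint, inter-infusion interval regularity, and the
multidose dose-response curve with its peak dose.  Writes
results/behavior_analysis.json and the per-subject acquisition table.
"""

from pathlib import Path

import pandas as pd

from dopakit.behavior import (
    COCAINE_FR1_CRITERIA,
    ScheduleSpec,
    acquisition_filter,
    breakpoint_from_log,
    dose_response,
    interval_stats,
    summarize_session,
    validate_log,
)
from dopakit.io import read_event_log_csv, write_json
from dopakit.simulate import AgentParams, gen_session

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = Path(__file__).resolve().parent.parent / "scratch" / "simulated"
SEED = 1
N_SUBJECTS = 8
N_DAYS = 10


def main() -> None:
    # 10-day FR1 training cohort with subject-to-subject rate variation
    rows = []
    acquired = 0
    for subj in range(N_SUBJECTS):
        agent = AgentParams(base_rate_hz=0.001 + 0.004 * subj)
        days = []
        for day in range(N_DAYS):
            log = gen_session(
                agent, ScheduleSpec.fr1_cocaine(), seed=SEED + 100 * subj + day
            )
            validate_log(log)
            days.append(summarize_session(log))
        res = acquisition_filter(days, COCAINE_FR1_CRITERIA)
        acquired += res.acquired
        rows.append(
            {
                "subject": subj,
                "mean_infusions": sum(d.infusions for d in days) / N_DAYS,
                "acquired": res.acquired,
                "acquisition_day": res.acquisition_day,
                "exclusion_reason": res.exclusion_reason,
            }
        )
    cohort = pd.DataFrame(rows)
    cohort.to_csv(ROOT / "acquisition_table.csv", index=False)
    print(f"acquisition: {acquired}/{N_SUBJECTS} subjects met criteria")
    print(cohort.to_string(index=False))

    pr_log = read_event_log_csv(SIM / "session_pr.csv")
    bp = breakpoint_from_log(pr_log)
    s = summarize_session(pr_log)
    print(f"PR session: {s.infusions} infusions, breakpoint {bp}")

    fr1_log = read_event_log_csv(SIM / "session_fr1.csv")
    iv = interval_stats(fr1_log)
    print(
        f"FR1 inter-infusion intervals: mean {iv.mean_s:.1f} s, "
        f"CV {iv.cv:.2f}, {len(iv.gaps_s)} gaps > 600 s"
    )

    md_log = read_event_log_csv(SIM / "session_multidose.csv")
    dr = dose_response(md_log)
    print("dose-response (mg/kg: infusions):")
    for d, n in zip(dr.doses, dr.infusions):
        print(f"  {d:g}: {n}")
    print(f"peak dose {dr.peak_dose} mg/kg, total intake {dr.total_intake_mg_kg:.2f} mg/kg")

    write_json(
        {
            "n_acquired": acquired,
            "n_subjects": N_SUBJECTS,
            "pr_infusions": s.infusions,
            "pr_breakpoint": bp,
            "fr1_interval_mean_s": iv.mean_s,
            "fr1_interval_cv": iv.cv,
            "dose_response": {
                "doses": dr.doses,
                "infusions": dr.infusions,
                "intake_mg_kg": dr.intake_mg_kg,
                "peak_dose": dr.peak_dose,
            },
        },
        ROOT / "behavior_analysis.json",
    )


if __name__ == "__main__":
    main()
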