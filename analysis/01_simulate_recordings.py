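#!/usr/bin/env python
"""Simulate the three synthetic data streams and write them under results/.

Produces one photometry recording (20 min, 5 min on / 1 min off duty
cycle), one evoked FSCV transient, and three operant sessions (FR1, PR,
multidose), each with its ground truth, for the downstream analysis
scripts.
"""

from pathlib import Path

from dopakit.behavior import ScheduleSpec, summarize_session
from dopakit.io import (
    write_event_log_csv,
    write_fscv_csv,
    write_ground_truth_json,
    write_photometry_csv,
)
from dopakit.simulate import (
    AgentParams,
    FscvSimParams,
    PhotometrySimParams,
    gen_fscv,
    gen_photometry,
    gen_session,
)

SEED = 1
# raw simulated traces are bulky; they go under scratch/, tables under results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    trace, truth = gen_photometry(PhotometrySimParams(), seed=SEED)
    write_photometry_csv(trace, OUT / "photometry_trace.csv")
    write_ground_truth_json(truth, OUT / "photometry_truth.json")
    print(
        f"photometry: {len(trace)} samples, "
        f"{100 * trace.mask.mean():.1f}% recorded, "
        f"{len(truth.event_times_s)} planted transients"
    )

    fscv_trace, fscv_truth = gen_fscv(FscvSimParams(), seed=SEED)
    write_fscv_csv(fscv_trace, OUT / "fscv_trace.csv")
    write_ground_truth_json(fscv_truth, OUT / "fscv_truth.json")
    print(
        f"fscv: peak {fscv_truth.event_amps[0]:.2f} uM planted, "
        f"tau {fscv_truth.params_echo['decay_tau_s']:.2f} s"
    )

    agent = AgentParams()
    for name, sched in [
        ("fr1", ScheduleSpec.fr1_cocaine()),
        ("pr", ScheduleSpec.pr_cocaine()),
        ("multidose", ScheduleSpec.multidose_cocaine()),
    ]:
        log = gen_session(agent, sched, seed=SEED)
        write_event_log_csv(log, OUT / f"session_{name}.csv")
        s = summarize_session(log)
        print(
            f"session {name}: {s.active_pokes} active / "
            f"{s.inactive_pokes} inactive pokes, {s.infusions} infusions, "
            f"intake {s.intake_mg_kg:.2f} mg/kg"
        )


if __name__ == "__main__":
    main()
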