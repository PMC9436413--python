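"""End-to-end pipeline: simulate every data stream, analyze it, write results.

``run_pipeline`` drives the three simulators and their matching analyses
with one seed, writing traces and event logs as CSV, summaries as JSON and
a manifest recording the configuration.  Output is deterministic given
(config, seed) apart from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Optional

from . import __version__
from .behavior import (
    ScheduleSpec,
    breakpoint_from_log,
    dose_response,
    summarize_session,
    validate_log,
)
from .fscv import fit_decay, peak_amplitude
from .io import (
    RunConfig,
    write_event_log_csv,
    write_fscv_csv,
    write_ground_truth_json,
    write_json,
    write_photometry_csv,
)
from .photometry import (
    DetectionParams,
    EpochSpec,
    compute_dff,
    detect_transients,
    epoch_compare,
    zscore,
)
from .simulate import (
    AgentParams,
    FscvSimParams,
    PhotometrySimParams,
    gen_fscv,
    gen_photometry,
    gen_session,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # propagate with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("photometry")
def _run_photometry(cfg: RunConfig, out: Path, seed: int) -> dict:
    params = PhotometrySimParams(**cfg.photometry)
    trace, truth = gen_photometry(params, seed=seed)
    write_photometry_csv(trace, out / "photometry_trace.csv")
    write_ground_truth_json(truth, out / "photometry_truth.json")
    dff = compute_dff(trace)
    zt = zscore(dff)
    det = DetectionParams(**cfg.detection)
    events = detect_transients(zt, det)
    half = params.duration_s / 2.0
    comparison = None
    try:
        comparison = epoch_compare(
            events,
            EpochSpec(0.0, half, "first_half"),
            EpochSpec(half, params.duration_s, "second_half"),
            zt,
        )
    except Exception:
        pass
    return {
        "n_planted": int(len(truth.event_times_s)),
        "n_detected": len(events),
        "control_fit_r2": [f.r2 for f in dff.fits],
        "epoch_rates_per_min": None
        if comparison is None
        else {
            "pre": comparison.rate_pre,
            "post": comparison.rate_post,
            "ratio": comparison.ratio,
        },
    }


@_stage("fscv")
def _run_fscv(cfg: RunConfig, out: Path, seed: int) -> dict:
    params = FscvSimParams(**cfg.fscv)
    trace, truth = gen_fscv(params, seed=seed)
    write_fscv_csv(trace, out / "fscv_trace.csv")
    write_ground_truth_json(truth, out / "fscv_truth.json")
    peak, t_peak = peak_amplitude(trace)
    fit = fit_decay(trace)
    return {
        "true_peak_um": params.peak_um,
        "measured_peak_um": peak,
        "true_tau_s": params.decay_tau_s,
        "fitted_tau_s": fit.tau_s,
        "fit_r2": fit.r2,
    }


@_stage("session")
def _run_sessions(cfg: RunConfig, out: Path, seed: int) -> dict:
    agent = AgentParams(**cfg.session)
    results: dict = {}
    fr1 = gen_session(agent, ScheduleSpec.fr1_cocaine(), seed=seed)
    validate_log(fr1)
    write_event_log_csv(fr1, out / "session_fr1.csv")
    s = summarize_session(fr1)
    results["fr1"] = {
        "active_pokes": s.active_pokes,
        "inactive_pokes": s.inactive_pokes,
        "infusions": s.infusions,
        "intake_mg_kg": s.intake_mg_kg,
    }
    pr = gen_session(agent, ScheduleSpec.pr_cocaine(), seed=seed + 1)
    validate_log(pr)
    write_event_log_csv(pr, out / "session_pr.csv")
    results["pr"] = {
        "infusions": summarize_session(pr).infusions,
        "breakpoint": breakpoint_from_log(pr),
    }
    md = gen_session(agent, ScheduleSpec.multidose_cocaine(), seed=seed + 2)
    validate_log(md)
    write_event_log_csv(md, out / "session_multidose.csv")
    dr = dose_response(md)
    results["multidose"] = {
        "doses": dr.doses,
        "infusions": dr.infusions,
        "intake_mg_kg": dr.intake_mg_kg,
        "peak_dose": dr.peak_dose,
    }
    return results


def run_pipeline(config: Optional[RunConfig] = None) -> dict:
    """Run simulate -> analyze for all three data streams.

    Returns the result bundle (also written to ``<out_dir>/summary.json``
    with a manifest at ``<out_dir>/manifest.json``).
    """
    cfg = config or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    bundle = {
        "photometry": _run_photometry(cfg, out, seed),
        "fscv": _run_fscv(cfg, out, seed),
        "sessions": _run_sessions(cfg, out, seed),
    }
    write_json(bundle, out / "summary.json")
    manifest = {
        "package": "dopakit",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "timestamp": datetime.datetime.now().isoformat(),
    }
    write_json(manifest, out / "manifest.json")
    return bundle
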