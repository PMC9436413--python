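# Methods

This note documents the models, parameter choices, numerical rules and
known limitations of the dopakit pipeline: dual-channel fiber-photometry
ΔF/F and transient detection, FSCV dopamine-release kinetics, and operant
self-administration schedule analytics, each paired with a synthetic-data
generator that plants known ground truth.

## Photometry

### Signal model (generator)

The generator emulates a dual-wavelength photometry rig recording a
dopamine sensor (465 nm excitation) and a dopamine-independent mCherry
control (560 nm) at 120 samples/s (12 ksps decimated by 100), in a
5 min on / 1 min off duty cycle (83% on-time). The model is

    F465(t) = B · bleach(t) · (1 + s(t)) + m(t) + n465(t)
    F560(t) = g · (B · bleach(t) + m(t)) + n560(t)
    bleach(t) = (1 − f) + f · exp(−t / τ_bleach)

with baseline fluorescence B = 100 a.u., bleach fraction f = 0.3 over
τ_bleach = 1500 s, a shared motion artifact m(t) (Gaussian noise smoothed
over 0.1 s, SD 0.5 a.u.), control gain g = 0.7, and per-channel noise
(SD 0.3 a.u.) bandlimited to 6 Hz — the acquisition chain low-pass
filters at 6 Hz, so recorded noise is bandlimited, not white. Dopamine
transients s(t) are a Poisson process (default 0.05 events/s) of
difference-of-exponentials kernels (1 − e^{−Δt/τ_r})·e^{−Δt/τ_d},
normalised to unit peak and scaled by the planted amplitude, with
τ_r = 50 ms and τ_d = 500 ms. Planting transients multiplicatively on the
bleach envelope makes the planted amplitude exactly the ΔF/F amplitude
the analysis should recover; the default 0.05 ΔF/F is ≈ 10× the ΔF/F
noise floor these settings produce. In vivo transient amplitude and
kinetics for GRAB-DA class sensors are not pinned by published numbers;
these defaults are placeholders in the physiological range and are echoed
into every dataset's ground truth.

What the generator does not emulate: sensor binding kinetics,
hemodynamic or spectral cross-talk, channel-specific bleaching, lock-in
demodulation residuals, or movement-correlated dopamine release. Passing
the recovery tests therefore shows the estimators are correct for this
artifact model, not that the correction handles every failure mode of
real recordings.

### ΔF/F

Recorded samples are split into contiguous duty-cycle blocks. Per block
(default; a whole-trace option exists) the sensor channel is regressed on
the control channel by ordinary least squares, and

    ΔF/F = (F465 − fit560) / fit560,  fit560 = slope·F560 + intercept.

The regression direction (control predicts sensor) is what makes
"subtract the fitted control from the sensor" dimensionally coherent;
"alignment" is the affine fit itself, no time-lag correction is applied.
Per-block fitting is the default because the photobleaching state differs
across blocks. Degenerate inputs raise: segments shorter than 10 samples,
a zero-variance control channel, or a fitted control ≤ 0 (reported with
the sample index). For any trace in which the sensor channel is an exact
affine function of the control channel, every ΔF/F sample is 0 to within
1e−9 (tested as a property).

### Transient detection

ΔF/F is z-scored against a reference population — each block's own
mean/SD by default, or the whole masked trace (`z_reference=GLOBAL`); the
criterion's wording admits both readings, so both are implemented. A
sample is an onset iff its z value exceeds the mean plus k·SD (k = 3) of
the z scores in the immediately preceding 0.5 s window, with the window
required to lie entirely inside the same block (hence no onset can occur
within one window of a block start), and subject to a 0.5 s refractory
period that prevents double-counting a single rising phase. The event
peak is the z maximum between the onset and the first return below the
onset window's mean — the original interactive event-detection software
does not publish its peak rule, so this definition is ours. The
implementation is verified sample-for-sample against a brute-force
re-computation of the windowed statistics at every sample.

**Operating characteristic.** Because the threshold adapts to the local
mean and SD, it is self-normalising: on Gaussian noise its false-onset
rate is invariant to both noise amplitude and bandwidth, measured at
~10 onsets/min at 120 samples/s with the 0.5 s refractory (white or 2–6 Hz
bandlimited noise alike). High-SNR planted transients are recalled at
≥ 0.95, but at a 3/min planted rate the noise floor bounds precision near
0.2–0.25 — no signal-to-noise choice changes this, since the false rate is
scale-free. Event counts produced by this rule should therefore be read
as *threshold-crossing rates* whose differences between conditions are
meaningful, not as censuses of true transients; a precision-oriented
detector would need a higher k, a longer reference window, or an absolute
amplitude gate. We keep the rule as defined and document the bound rather
than silently re-tuning it.

### Epoch rates

Transient frequency over an epoch divides onset counts by the *recorded*
(masked-on) minutes within the epoch, so duty-cycle gaps do not dilute
rates. Epoch comparisons return (rate_pre, rate_post, ratio); a zero
baseline rate flags the ratio undefined rather than returning infinity.
An optional zero-phase 6 Hz Butterworth low-pass is available for raw
synthetic traces but is off by default (acquisition already bandlimits).

## FSCV

The module operates on extracted oxidation-current or concentration time
series, one sample per 100 ms scan; voltammogram-level processing is out
of scope. Electrode calibration fits current = slope·concentration +
intercept over standards (typically 0.1–2 µM dopamine); a non-positive
slope raises (electrode fault), and conversions outside the calibration
range are flagged, never clipped.

Evoked-release metrics: baseline is the mean over the 1 s preceding the
stimulus (shorter than the 2 min inter-stimulus interval, long enough to
average noise); the peak is the maximum above baseline within a 2 s
post-stimulus search window. The decay constant is obtained by nonlinear
least squares of C(t) = baseline + A·e^{−(t−t_peak)/τ} from the peak to
the first sample at or below baseline + 0.1·A (configurable
`fit_fraction`) or the trace end, with initial values A₀ = measured
peak, τ₀ = time-to-half-peak / ln 2, baseline₀ = pre-stimulus mean, and
bounds A ≥ 0, τ > 0. The acquisition software used for such recordings
does not publish its τ algorithm or window; this stop rule is our
definition, stated rather than inferred. Fits with amplitude at or below
3× the pre-stimulus noise SD raise a degenerate-fit error; non-convergence
raises with diagnostics. The estimator is scale-equivariant (amplitude
scales, τ invariant) and time-shift invariant (tested as properties), and
recovers τ ∈ {0.3, 0.6, 1.2} s with ≈ 4–5% median relative error over 100
seeds at the default noise (0.02 µM on a 1 µM peak).

The generator uses a linear 0.2 s rise to the peak followed by the
exponential decay; five-pulse 100 Hz trains superpose five kernels 10 ms
apart. Stimulus electrical parameters are metadata, not simulated.

## Operant schedules

### Schedule semantics (generator and validators)

FR1: every active poke outside a timeout triggers an infusion, a 5 s cue
and a 10 s timeout, cue and timeout both starting at the reinforced poke
(one 10 s lockout — the source wording is ambiguous about overlap).
Pokes during timeouts are recorded but have no consequence. Sessions are
3 hr (1 hr for sucrose) and end early at 64 reinforcers. Pump duration
scales proportionally with dose, anchored at 1.0 mg/kg ↔ 7.07 s,
rounded half-away-from-zero to 2 decimals — reproducing the published
7.07/1.77/0.88/0.44/0.22/0 s table for the descending-dose series. (The
0.5 mg/kg training dose is an exact half, 3.535 s; the rule gives 3.54
where conventional tables print 3.53.)

Multidose sessions open with a 30 min trial at the 0.5 mg/kg training
dose, then six 30 min trials at 1.0, 0.25, 0.125, 0.0625, 0.03125 and
0.0 mg/kg, separated by 1 min intertrial timeouts; the reinforcer cap is
disabled by default for this schedule, since a 64 cap across seven trials
would truncate the dose-response curve mid-session (the early-stop rule
is stated for 3 hr single-dose sessions).

PR: the response requirement for the n-th infusion is
round(5·(e^{0.18·n} − 1)), half-away-from-zero, floored at 1, yielding
1, 2, 4, 5, 7, 10, 13, 16, 20, 25, 31, 38, 47, 57, 69, 84, 102, … The
conventionally printed series opens with a duplicated 1; whether that
reflects a free first reinforcer is not stated, so `pr_series` defaults
to the formula and offers the printed variant behind
`leading_free_reinforcer`. The breakpoint is the requirement completed
for the last infusion before the first ≥ 1 hr infusion-free interval
(including the interval from session start and the terminal interval; a
terminal gap shorter than 1 hr does not truncate; no infusions → 0).
`validate_log` replays every generated log against these rules — timeout
spacing, cap, and the exact PR requirement counts.

### Criteria

Cocaine FR1 acquisition: ≥ 25 infusions and > 2:1 active/inactive ratio
for 3 consecutive days, and ≤ 20% variability in infusions across the two
closing days of the window, within 10 training sessions. The variability
comparator is |a−b| / mean(a,b) — the denominator is not specified in
common usage, so it is configurable. A zero inactive count with active
responding passes the ratio test (ratio = +∞). The sucrose variant uses
≥ 30 rewards over 4 consecutive days that must include the last training
day. Multidose stability: total infusions vary ≤ 20% across two
consecutive sessions and the dose of maximal responding drifts ≤ 0.5
log10 units. The filter is monotone in infusion counts (tested as a
property).

### Agent model

The simulated animal is deliberately minimal: Poisson responding at an
exploratory floor plus a reward-maintained component coupled to unit dose
by a Hill function (base 0.1 Hz, d50 = 0.15 mg/kg, Hill 2), a
post-infusion satiety pause of 150 s per mg/kg, and on PR a constant quit
hazard of 0.01 per counted poke. These four mechanisms were chosen from a
closed-form cycle-time argument (inter-infusion time ≈ 1/rate + timeout +
pause·dose) so that per-trial infusions form an inverted-U over the dose
series with the maximum at 0.125 mg/kg, as observed for cocaine; the
dose-coupling fields extend the minimal rate+pause+hazard parameterisation,
which on its own yields infusions monotone decreasing in dose. A
deterministic metronome mode (`deterministic_interval_s`) replaces the
stochastic stream for worked examples and cap checks. The agent exists to
exercise schedule analytics; it is not a pharmacokinetic or behavioral
model of cocaine.

## Numerical and reproducibility choices

- One `numpy.random.default_rng(seed)` per generator call; identical
  (params, seed) give bit-identical outputs; no global random state.
- Rounding is half-away-from-zero wherever integer requirements or
  2-decimal durations are produced (Python's round() is half-even and
  would break the published series).
- Windowed detection statistics use population SD (ddof = 0); windows are
  `round(window_s · fs)` samples.
- CSV is written at full precision (%.17g); write→read round-trips are
  exact on metadata and ≤ 1e−12 on values.
- Problem sizes in the test-suite studies (20 min photometry recordings,
  100-seed τ grids, 1000 random PR logs, 100×10⁴-sample oracle
  comparisons) were chosen as the smallest sizes at which the statistical
  assertions are stable across seeds.

## Known limitations

- The transient detector's precision bound on Gaussian noise (above) is
  intrinsic to the adaptive rule, and event counts are threshold-crossing
  rates, not transient censuses.
- The control-channel fit removes only artifacts that are affine-shared
  between channels within a block; channel-specific bleaching or
  nonlinear motion coupling would leave residuals.
- τ fitting assumes a single-exponential clearance; multi-phasic decays
  or strongly overlapping train responses are out of scope.
- The agent model makes no claim about real response rates or
  pharmacology; cohort-level numbers from it are illustrative only.
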