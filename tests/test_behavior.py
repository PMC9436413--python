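"""Operant schedule analytics: requirement series, breakpoint, summaries,
acquisition and stability filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_log
from dopakit.behavior import (
    COCAINE_FR1_CRITERIA,
    SUCROSE_FR1_CRITERIA,
    DoseResponse,
    MultidoseStability,
    ScheduleSpec,
    ScheduleError,
    SessionSummary,
    acquisition_filter,
    breakpoint_from_log,
    dose_response,
    infusion_duration,
    interval_stats,
    multidose_stable,
    pr_requirement,
    pr_series,
    summarize_session,
    validate_log,
)

# The progressive-ratio requirement series as conventionally printed:
# round(5 * (exp(0.18 * n) - 1)) for n = 1..18, preceded by a duplicate 1.
PRINTED_PR_SERIES = [1, 1, 2, 4, 5, 7, 10, 13, 16, 20, 25, 31, 38, 47, 57, 69, 84, 102]


class TestPrRequirement:
    @pytest.mark.parametrize("n,expected", [(1, 1), (11, 31), (17, 102)])
    def test_published_values(self, n, expected):
        assert pr_requirement(n) == expected

    def test_series_matches_printed_sequence(self):
        # formula series == printed entries 2..18 (printed opens with an
        # extra requirement-1 entry)
        assert pr_series(17) == PRINTED_PR_SERIES[1:]
        assert pr_series(17, leading_free_reinforcer=True) == PRINTED_PR_SERIES

    def test_series_nondecreasing_and_floored(self):
        s = pr_series(200)
        assert all(b >= a for a, b in zip(s, s[1:]))
        assert all(v >= 1 for v in s)

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            pr_requirement(0)
        with pytest.raises(ValueError):
            pr_series(0)


class TestBreakpoint:
    def test_no_infusions_is_zero(self):
        log = make_log(ScheduleSpec.pr_cocaine())
        assert breakpoint_from_log(log) == 0

    def test_gap_truncates_requirement(self):
        # 4 infusions completed, then a 2 hr pause, then a 5th: the
        # breakpoint is the 4th requirement, not the 5th
        times = [100, 300, 700, 1500, 1500 + 7200 + 10]
        log = make_log(ScheduleSpec.pr_cocaine(), infusion_times=times)
        assert breakpoint_from_log(log) == pr_requirement(4)

    def test_short_terminal_gap_does_not_truncate(self):
        # 7 infusions evenly spaced to near session end (requirement 13)
        times = list(np.linspace(100, 10700, 7))
        log = make_log(ScheduleSpec.pr_cocaine(), infusion_times=times)
        assert breakpoint_from_log(log) == pr_requirement(7) == 13

    def test_initial_hour_without_infusions(self):
        log = make_log(
            ScheduleSpec.pr_cocaine(), infusion_times=[4000.0, 4100.0]
        )
        assert breakpoint_from_log(log) == 0

    def test_requires_pr_schedule(self):
        log = make_log(ScheduleSpec.fr1_cocaine(), infusion_times=[10.0])
        with pytest.raises(ScheduleError):
            breakpoint_from_log(log)

    def test_agrees_with_brute_force_scan(self):
        # oracle: enumerate every infusion-free interval directly
        rng = np.random.default_rng(7)
        sched = ScheduleSpec.pr_cocaine()
        for _ in range(200):
            n = int(rng.integers(0, 12))
            times = np.sort(rng.uniform(0, sched.session_s, n))
            if n > 1:
                times = times[
                    np.concatenate([[True], np.diff(times) > sched.timeout_s])
                ]
            log = make_log(sched, infusion_times=list(times))
            bounds = [0.0] + list(times) + [sched.session_s]
            expected = pr_requirement(len(times)) if len(times) else 0
            for k in range(len(bounds) - 1):
                if bounds[k + 1] - bounds[k] >= 3600.0:
                    expected = pr_requirement(k) if k else 0
                    break
            assert breakpoint_from_log(log) == expected


class TestSummaries:
    def test_empty_log_all_zero(self):
        s = summarize_session(make_log(ScheduleSpec.fr1_cocaine()))
        assert (s.active_pokes, s.inactive_pokes, s.infusions) == (0, 0, 0)
        assert s.intake_mg_kg == 0.0

    def test_intake_is_dose_weighted_sum(self):
        log = make_log(
            ScheduleSpec.fr1_cocaine(),
            infusion_times=np.arange(10) * 100.0,
            doses=[0.5] * 10,
        )
        assert summarize_session(log).intake_mg_kg == pytest.approx(5.0)

    def test_multidose_intake_decomposition(self):
        log = make_log(
            ScheduleSpec(kind="MULTIDOSE", dose_sequence=(1.0, 0.25), cap=None),
            infusion_times=[10, 50, 2000, 2100, 2200, 2300],
            doses=[1.0, 1.0, 0.25, 0.25, 0.25, 0.25],
            trial_ids=[0, 0, 1, 1, 1, 1],
        )
        s = summarize_session(log)
        assert s.intake_mg_kg == pytest.approx(3.0)
        assert s.per_dose[1.0] == (2, 2.0)
        assert s.per_dose[0.25] == (4, 1.0)
        # conservation: total equals the per-dose decomposition
        assert s.intake_mg_kg == pytest.approx(
            sum(v[1] for v in s.per_dose.values())
        )


def _summary(infusions, active=100, inactive=10):
    return SessionSummary(
        active_pokes=active,
        inactive_pokes=inactive,
        infusions=infusions,
        intake_mg_kg=infusions * 0.5,
    )


class TestAcquisition:
    def test_steady_responding_acquires_day_three(self):
        days = [_summary(30, active=30, inactive=10) for _ in range(10)]
        res = acquisition_filter(days, COCAINE_FR1_CRITERIA)
        assert res.acquired and res.acquisition_day == 3

    def test_no_responding_excluded_for_min_infusions(self):
        days = [_summary(0, active=0, inactive=0) for _ in range(10)]
        res = acquisition_filter(days)
        assert not res.acquired and res.exclusion_reason == "min_infusions"

    def test_variable_intake_blocks_acquisition_day(self):
        # |40 - 20| / 30 = 0.667 > 0.20 fails the stability rule on day 3
        # |25 - 40| / 32.5 = 0.46 > 0.20 blocks day 3; |26 - 25| / 25.5
        # passes on day 4.  A (40, 20) closing pair (variability 0.667)
        # likewise blocks acquisition outright.
        days = [_summary(40), _summary(40), _summary(25), _summary(26)]
        assert acquisition_filter(days).acquisition_day == 4
        assert not acquisition_filter(
            [_summary(40), _summary(40), _summary(20)]
        ).acquired

    def test_ratio_criterion(self):
        days = [_summary(30, active=30, inactive=20) for _ in range(10)]
        res = acquisition_filter(days)
        assert not res.acquired and res.exclusion_reason == "ratio"

    def test_zero_inactive_passes_ratio(self):
        days = [_summary(30, active=30, inactive=0) for _ in range(3)]
        assert acquisition_filter(days).acquired

    def test_sucrose_variant_requires_last_day(self):
        # 4 good days early, then a collapse: the 4-day window must include
        # the last training day, so the subject does not acquire
        days = [_summary(35)] * 4 + [_summary(0, active=0)] * 6
        res = acquisition_filter(days, SUCROSE_FR1_CRITERIA)
        assert not res.acquired
        good = [_summary(35)] * 10
        res = acquisition_filter(good, SUCROSE_FR1_CRITERIA)
        assert res.acquired and res.acquisition_day == 10

    @given(boost=st.integers(min_value=0, max_value=50))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_infusions(self, boost):
        # raising every day's infusion count (ratios held) never converts
        # acquired -> not acquired
        base = [28, 30, 29, 31, 30, 28, 29, 30, 31, 30]
        low = acquisition_filter([_summary(b) for b in base])
        high = acquisition_filter([_summary(b + boost) for b in base])
        assert high.acquired >= low.acquired


class TestDoseScaling:
    @pytest.mark.parametrize(
        "dose,expected",
        [(1.0, 7.07), (0.25, 1.77), (0.125, 0.88), (0.0625, 0.44),
         (0.03125, 0.22), (0.0, 0.0)],
    )
    def test_published_durations(self, dose, expected):
        assert infusion_duration(dose) == pytest.approx(expected)

    def test_training_dose_rounds_the_exact_half_up(self):
        # 7.07 / 2 = 3.535 is an exact half: half-away-from-zero gives
        # 3.54 (conventional tables print 3.53 for this dose)
        assert infusion_duration(0.5) == pytest.approx(3.54)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            infusion_duration(-0.1)


class TestDoseResponse:
    DOSES = (0.5, 1.0, 0.25, 0.125, 0.0625, 0.03125, 0.0)

    def _log_with_counts(self, counts):
        sched = ScheduleSpec.multidose_cocaine()
        times, doses, tids, starts = [], [], [], []
        t = 0.0
        for tid, (dose, cnt) in enumerate(zip(self.DOSES, counts)):
            starts.append((t, dose))
            for j in range(cnt):
                times.append(t + 20.0 * (j + 1))
                doses.append(dose)
                tids.append(tid)
            t += sched.trial_s + sched.intertrial_s
        return make_log(
            sched, infusion_times=times, doses=doses, trial_ids=tids,
            trial_starts=starts,
        )

    def test_inverted_u_argmax(self):
        counts = (2, 5, 9, 12, 8, 4, 1)
        dr = dose_response(self._log_with_counts(counts))
        assert dr.peak_dose == 0.125
        assert dr.infusions == list(counts)
        assert dr.total_intake_mg_kg == pytest.approx(
            sum(c * d for c, d in zip(counts, self.DOSES))
        )

    def test_zero_responding_flagged(self):
        dr = dose_response(self._log_with_counts((0,) * 7))
        assert dr.peak_dose is None and dr.total_infusions == 0

    def test_missing_trial_markers_rejected(self):
        sched = ScheduleSpec.multidose_cocaine()
        log = make_log(sched, infusion_times=[10.0], doses=[0.5])
        with pytest.raises(ScheduleError):
            dose_response(log)


class TestMultidoseStability:
    def _dr(self, counts, doses=(0.5, 1.0, 0.25, 0.125, 0.0625, 0.03125, 0.0)):
        return DoseResponse(
            list(doses), list(counts),
            [c * d for c, d in zip(counts, doses)],
            peak_dose=doses[int(np.argmax(counts))] if any(counts) else None,
        )

    def test_identical_sessions_stable(self):
        a = self._dr((2, 5, 9, 12, 8, 4, 1))
        assert multidose_stable(a, a).stable

    def test_high_variation_unstable(self):
        a = self._dr((10, 10, 10, 10, 5, 3, 2))  # 50 total
        b = self._dr((20, 20, 15, 15, 5, 3, 2))  # 80 total
        res = multidose_stable(a, b)
        assert not res.stable
        assert res.infusion_variation == pytest.approx(abs(50 - 80) / 65)

    def test_half_log_dose_drift_allowed(self):
        a = self._dr((2, 5, 9, 12, 8, 4, 1))   # peak at 0.125
        b = self._dr((2, 5, 12, 9, 8, 4, 1))   # peak at 0.25
        res = multidose_stable(a, b)
        assert res.dose_drift_log10 == pytest.approx(math.log10(2), abs=1e-12)
        assert res.stable  # variation 0, drift 0.301 <= 0.5

    def test_empty_sessions_flagged_undefined(self):
        a = self._dr((0,) * 7)
        assert multidose_stable(a, a).undefined


class TestIntervalStats:
    def test_periodic_infusions_cv_zero(self):
        log = make_log(
            ScheduleSpec.fr1_cocaine(), infusion_times=np.arange(20) * 60.0
        )
        st_ = interval_stats(log)
        assert st_.cv == pytest.approx(0.0)

    def test_hand_computed_intervals(self):
        log = make_log(
            ScheduleSpec.fr1_cocaine(), infusion_times=[0.0, 10.0, 20.0, 120.0]
        )
        st_ = interval_stats(log)
        iv = np.array([10.0, 10.0, 100.0])
        assert st_.mean_s == pytest.approx(40.0)
        assert st_.cv == pytest.approx(iv.std() / iv.mean())

    def test_single_infusion_flagged(self):
        log = make_log(ScheduleSpec.fr1_cocaine(), infusion_times=[10.0])
        assert not interval_stats(log).defined


class TestValidation:
    def test_infusions_inside_timeout_rejected(self):
        log = make_log(ScheduleSpec.fr1_cocaine(), infusion_times=[10.0, 15.0])
        with pytest.raises(ScheduleError):
            validate_log(log)

    def test_cap_violation_rejected(self):
        sched = ScheduleSpec(kind="FR1", cap=3)
        log = make_log(sched, infusion_times=[10.0, 30.0, 50.0, 70.0])
        with pytest.raises(ScheduleError):
            validate_log(log)

    def test_unknown_schedule_kind_rejected(self):
        with pytest.raises(ScheduleError):
            ScheduleSpec(kind="FR7")
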