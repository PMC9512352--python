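import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapdvh.dvh import dvh_statistic
from gapdvh.errors import CalendarError, InvalidParameterError
from gapdvh.phantom import C1_TUMOR, build_case_study
from gapdvh.planner import (
    PlanSegment,
    TreatmentCalendar,
    TreatmentSession,
    bid_session_groups,
    build_calendar,
    evaluate_plan,
    overall_time,
    point_dose_rcr,
    scale_dvh_dose,
    validate_schedule,
)
from gapdvh.radiobiology import (
    ScheduleSummary,
    TissueParams,
    bed_scalar,
    eqd2_from_bed,
    round_report,
)

MON = dt.date(2021, 5, 3)  # a Monday
AM, PM = dt.time(9, 0), dt.time(15, 0)


def day(i):
    return MON + dt.timedelta(days=i)


def single_daily(n, start=MON, d=2.0, weekends=False):
    sessions = []
    current = start
    while len(sessions) < n:
        if weekends or current.weekday() < 5:
            sessions.append(TreatmentSession(current, AM, d))
        current += dt.timedelta(days=1)
    return TreatmentCalendar(tuple(sessions))


class TestOverallTime:
    def test_single_day(self):
        cal = TreatmentCalendar((TreatmentSession(MON, AM, 2.0),))
        assert overall_time(cal) == 1

    def test_inclusive_count(self):
        cal = TreatmentCalendar((
            TreatmentSession(day(0), AM, 2.0),
            TreatmentSession(day(13), AM, 2.0),
        ))
        assert overall_time(cal) == 14

    def test_patient_c_resumption(self):
        """The gap days sit inside the inclusive span: T covers the gap."""
        case = build_case_study("C")
        pre = single_daily(case.pre_gap.N)
        gap_start = pre.sessions[-1].date + dt.timedelta(days=1)
        skip = [gap_start + dt.timedelta(days=i) for i in range(case.gap_days)]
        rest = build_calendar(gap_start, case.post_gap.N, 2.0, skip=skip)
        whole = TreatmentCalendar(pre.sessions + rest.sessions)
        assert whole.n_fractions == 35
        span = (whole.sessions[-1].date - whole.sessions[0].date).days + 1
        assert overall_time(whole) == span
        assert overall_time(whole) > overall_time(rest)

    def test_resumed_course_ending_at_day_63(self):
        """A course whose last session falls on day 62 has T = 63."""
        sessions = [TreatmentSession(day(0), AM, 2.0)]
        sessions += [TreatmentSession(day(3 + i), AM, 2.0) for i in range(33)]
        sessions += [TreatmentSession(day(62), AM, 2.0)]
        assert overall_time(TreatmentCalendar(tuple(sessions))) == 63

    def test_empty_rejected(self):
        with pytest.raises(CalendarError):
            overall_time(TreatmentCalendar(()))


class TestCalendarInvariants:
    def test_three_sessions_per_day_rejected(self):
        with pytest.raises(CalendarError):
            TreatmentCalendar((
                TreatmentSession(MON, dt.time(8), 2.0),
                TreatmentSession(MON, dt.time(12), 2.0),
                TreatmentSession(MON, dt.time(16), 2.0),
            ))

    def test_duplicate_times_rejected(self):
        with pytest.raises(CalendarError):
            TreatmentCalendar((
                TreatmentSession(MON, AM, 2.0),
                TreatmentSession(MON, AM, 2.0),
            ))

    def test_twice_daily_count(self):
        cal = TreatmentCalendar((
            TreatmentSession(day(0), AM, 2.0),
            TreatmentSession(day(0), PM, 2.0),
            TreatmentSession(day(1), AM, 2.0),
        ))
        assert cal.twice_daily_days == [day(0)]
        assert cal.summary().TD == 1


class TestValidateSchedule:
    def test_six_per_week_alternating_bid_clean(self):
        cal = TreatmentCalendar((
            TreatmentSession(day(0), AM, 2.0),
            TreatmentSession(day(0), PM, 2.0),
            TreatmentSession(day(1), AM, 2.0),
            TreatmentSession(day(2), AM, 2.0),
            TreatmentSession(day(2), PM, 2.0),
            TreatmentSession(day(3), AM, 2.0),
        ))
        assert validate_schedule(cal) == []

    def test_seven_fractions_in_a_week(self):
        cal = single_daily(7, weekends=True)
        violations = validate_schedule(cal)
        assert len(violations) == 1
        assert "exceeds 6/week" in violations[0]

    def test_consecutive_bid_days_flagged(self):
        cal = TreatmentCalendar((
            TreatmentSession(day(0), AM, 2.0),
            TreatmentSession(day(0), PM, 2.0),
            TreatmentSession(day(1), AM, 2.0),
            TreatmentSession(day(1), PM, 2.0),
        ))
        violations = validate_schedule(cal)
        assert any("consecutive" in v for v in violations)

    def test_short_interval_flagged(self):
        cal = TreatmentCalendar((
            TreatmentSession(MON, dt.time(9), 2.0),
            TreatmentSession(MON, dt.time(13), 2.0),
        ))
        violations = validate_schedule(cal)
        assert any("below 6 h" in v for v in violations)


class TestBuildCalendar:
    def test_weekday_layout(self):
        cal = build_calendar(MON, 10, 2.0)
        assert cal.n_fractions == 10
        assert overall_time(cal) == 12  # two weekends excluded
        assert validate_schedule(cal) == []

    def test_bid_days_never_consecutive(self):
        cal = build_calendar(MON, 12, 2.0, bid_days=4)
        assert len(cal.twice_daily_days) == 4
        assert validate_schedule(cal) == []

    def test_six_per_week(self):
        cal = build_calendar(MON, 12, 2.0, treatment_days_per_week=6)
        assert validate_schedule(cal) == []
        assert overall_time(cal) < overall_time(build_calendar(MON, 12, 2.0))

    def test_invalid_args(self):
        with pytest.raises(InvalidParameterError):
            build_calendar(MON, 0, 2.0)
        with pytest.raises(InvalidParameterError):
            build_calendar(MON, 4, 2.0, bid_days=3)


class TestEvaluatePlanScalar:
    def intended(self, case):
        return [PlanSegment("full course", case.intended.N, case.intended.d,
                            case.intended.T)]

    def uncompensated(self, case):
        return [
            PlanSegment("pre-gap", case.pre_gap.N, case.pre_gap.d, case.pre_gap.T),
            PlanSegment("post-gap", case.post_gap.N, case.post_gap.d,
                        case.post_gap.T),
        ]

    def test_patient_c_differences(self):
        case = build_case_study("C")
        intended = evaluate_plan(self.intended(case), C1_TUMOR, label="intended")
        uncomp = evaluate_plan(self.uncompensated(case), C1_TUMOR,
                               label="uncompensated")
        assert round_report(intended.total.bed) == 64.2
        assert round_report(intended.total.eqd2) == 53.5
        assert round_report(uncomp.total.eqd2) == 43.8
        diff = uncomp.difference(intended)
        assert diff["bed"] == 11.7
        assert diff["eqd2"] == 9.7

    def test_patient_e_uncompensated(self):
        case = build_case_study("E")
        uncomp = evaluate_plan(self.uncompensated(case), C1_TUMOR)
        assert round_report(uncomp.total.eqd2) == 44.3
        intended = evaluate_plan(self.intended(case), C1_TUMOR)
        assert round_report(intended.total.bed) == 58.5

    def test_patient_b_post_gap_row(self):
        case = build_case_study("B")
        uncomp = evaluate_plan(self.uncompensated(case), C1_TUMOR)
        post = uncomp.rows[1]
        assert round_report(post.bed) == -2.1
        assert round_report(post.eqd2) == -1.8
        assert round_report(post.dose_lost) == 27.9

    def test_pre_gap_loss_zero_before_onset(self):
        case = build_case_study("A")
        uncomp = evaluate_plan(self.uncompensated(case), C1_TUMOR)
        assert uncomp.rows[0].dose_lost == 0.0  # T = 26 < onset at 28

    def test_reference_compared_with_itself(self):
        case = build_case_study("D")
        ev = evaluate_plan(self.intended(case), C1_TUMOR)
        assert ev.difference(ev) == {"bed": 0.0, "eqd2": 0.0}

    def test_overlapping_segments_rejected(self):
        with pytest.raises(CalendarError):
            evaluate_plan(
                [PlanSegment("a", 5, 2.0, 20.0), PlanSegment("b", 5, 2.0, 15.0)],
                C1_TUMOR,
            )

    def test_empty_plan_rejected(self):
        with pytest.raises(CalendarError):
            evaluate_plan([], C1_TUMOR)


class TestPointDose:
    def test_matches_bed_scalar(self):
        sched = ScheduleSummary(35, 2.0, 50.0)
        result = point_dose_rcr(2.0, sched, C1_TUMOR)
        bed = bed_scalar(70.0, sched, C1_TUMOR)
        assert result["bed"] == bed.value
        assert result["eqd2"] == eqd2_from_bed(bed, C1_TUMOR)
        assert round_report(result["bed"]) == 64.2

    def test_overestimates_oar_d2_on_gradient(self, uniform_dvh_factory):
        """Point dose at/above Dmax bounds the DVH-derived D2% EQD2."""
        from gapdvh.dvh import DVH
        from gapdvh.radiobiology import convert_dvh

        oar = TissueParams("oar", alpha_beta=3.0, tissue_class="oar")
        edges = np.arange(0.0, 51.0, 1.0)
        vols = np.ones(50)  # linear-gradient-like spread 0..50 Gy
        dvh = DVH("oar", edges, vols)
        schedule = ScheduleSummary(25, 2.0, 33.0)
        eqd2_dvh = convert_dvh(dvh, schedule, oar)
        d2 = dvh_statistic(eqd2_dvh, "D_x%", 2.0)
        d_max = dvh_statistic(dvh, "Dmax") / schedule.N
        point = point_dose_rcr(d_max, schedule, oar)
        assert point["eqd2"] >= d2


class TestSessionGroups:
    def test_tumor_always_h_zero(self):
        assert bid_session_groups(20, 3, C1_TUMOR, 6.0) == [(20, 0.0)]

    def test_oar_split(self):
        oar = TissueParams("oar", alpha_beta=3.0, tissue_class="oar")
        groups = bid_session_groups(20, 3, oar, 6.0)
        assert groups == [(6, 0.125), (14, 0.0)]

    def test_no_bid(self):
        oar = TissueParams("oar", alpha_beta=3.0, tissue_class="oar")
        assert bid_session_groups(20, 0, oar, 6.0) == [(20, 0.0)]


class TestMonotonicity:
    def test_ptv_eqd2_non_decreasing_as_t_shrinks(self):
        base = evaluate_plan([PlanSegment("p", 30, 2.0, 55.0)], C1_TUMOR)
        values = [
            evaluate_plan([PlanSegment("p", 30, 2.0, t)], C1_TUMOR).total.eqd2
            for t in (55.0, 50.0, 44.0, 40.0)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] >= base.total.eqd2

    def test_increasing_d_raises_both_ptv_and_oar(self):
        oar = TissueParams("oar", alpha_beta=3.0, tissue_class="oar")
        for params in (C1_TUMOR, oar):
            values = [
                evaluate_plan([PlanSegment("p", 18, d, 50.0)], params).total.eqd2
                for d in (2.0, 2.2, 2.5)
            ]
            assert values[0] < values[1] < values[2]

    def test_oar_eqd2_increases_with_td(self, uniform_dvh_factory):
        """More twice-daily days -> stepwise higher OAR dose (direction only)."""
        oar = TissueParams("oar", alpha_beta=3.0, tissue_class="oar")
        dvh = uniform_dvh_factory(40.0, 25.0)
        from gapdvh.radiobiology import convert_dvh

        d2_values = []
        for td in range(5):
            schedule = ScheduleSummary(20, 2.0, 26.0, TD=td, m=6.0)
            groups = bid_session_groups(20, td, oar, 6.0)
            out = convert_dvh(dvh, schedule, oar, groups)
            d2_values.append(dvh_statistic(out, "D_x%", 2.0))
        assert all(b > a for a, b in zip(d2_values, d2_values[1:]))

    @given(st.integers(1, 40), st.floats(1.5, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_scalar_and_dvh_mode_agree_on_uniform(self, n, d):
        from tests.conftest import uniform_dvh

        dvh = uniform_dvh(n * d, 30.0)
        seg = PlanSegment("p", n, d, max(1.0, 1.4 * n))
        scalar = evaluate_plan([seg], C1_TUMOR)
        dvh_mode = evaluate_plan([seg], C1_TUMOR, dvh=dvh)
        assert dvh_mode.headline["Dmax"] == pytest.approx(
            scalar.total.eqd2, abs=1e-9
        )


class TestDvhMode:
    def test_revised_plan_scales_reference_dvh(self, uniform_dvh_factory):
        case = build_case_study("C")
        ptv = uniform_dvh_factory(70.0, 80.0)
        revised = evaluate_plan(
            [PlanSegment("post", 29, 2.0, 56.0)],
            C1_TUMOR, dvh=ptv, reference_dose=70.0,
        )
        assert revised.dvh is not None
        assert revised.dvh.scale_tag == "EQD2"
        # 58 of 70 Gy delivered: physical dose axis scaled before conversion
        expected_bed = 58.0 * (1 + 2.0 / 10.0) - 0.9 * (56.0 - 28.0)
        assert revised.headline["Dmax"] == pytest.approx(expected_bed / 1.2)

    def test_scale_dvh_dose_guard(self, uniform_dvh_factory):
        with pytest.raises(InvalidParameterError):
            scale_dvh_dose(uniform_dvh_factory(10.0, 5.0), 0.0)
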