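"""Treatment calendars, compensation schedules, and plan evaluation.

Calendars hold dated, timed fraction sessions; schedule validation flags the
published gap-compensation constraints (at most 6 fractions per ISO week, no
twice-daily fractionation on consecutive treatment days, same-day sessions
at least 6 h apart).  ``evaluate_plan`` produces the segment-accounting rows
(per-segment BED/EQD2 with cumulatively attributed repopulation loss) used
to compare intended, uncompensated, and revised courses, in scalar or DVH
mode; ``point_dose_rcr`` is the 1-D point-dose method kept for comparison.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .dvh import DVH, dvh_statistic
from .errors import CalendarError, ConsistencyError, InvalidParameterError
from .radiobiology import (
    ScheduleSummary,
    TissueParams,
    bed_scalar,
    convert_dvh,
    eqd2_from_bed,
    incomplete_repair_factor,
    repopulation_loss,
    round_report,
)

__all__ = [
    "TreatmentSession",
    "TreatmentCalendar",
    "build_calendar",
    "overall_time",
    "validate_schedule",
    "PlanSegment",
    "PlanRow",
    "PlanEvaluation",
    "evaluate_plan",
    "point_dose_rcr",
    "scale_dvh_dose",
    "bid_session_groups",
]

MIN_INTERVAL_H = 6.0
MAX_FRACTIONS_PER_WEEK = 6


@dataclass(frozen=True, order=True)
class TreatmentSession:
    date: dt.date
    time: dt.time
    dose: float  # Gy

    @property
    def when(self) -> dt.datetime:
        return dt.datetime.combine(self.date, self.time)


@dataclass(frozen=True)
class TreatmentCalendar:
    """An ordered list of fraction sessions; gaps are simply dates without
    sessions."""

    sessions: tuple[TreatmentSession, ...]

    def __post_init__(self) -> None:
        sessions = tuple(sorted(self.sessions))
        object.__setattr__(self, "sessions", sessions)
        times = [s.when for s in sessions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CalendarError("sessions must be strictly ordered in time")
        for date, count in self._per_day().items():
            if count > 2:
                raise CalendarError(f"more than 2 sessions on {date}")

    def _per_day(self) -> dict[dt.date, int]:
        counts: dict[dt.date, int] = {}
        for s in self.sessions:
            counts[s.date] = counts.get(s.date, 0) + 1
        return counts

    @property
    def n_fractions(self) -> int:
        return len(self.sessions)

    @property
    def twice_daily_days(self) -> list[dt.date]:
        return sorted(d for d, c in self._per_day().items() if c == 2)

    @property
    def total_dose(self) -> float:
        return sum(s.dose for s in self.sessions)

    def summary(self, m_hours: float = MIN_INTERVAL_H) -> ScheduleSummary:
        """Collapse to (N, d, T, TD, m); requires a single dose per fraction."""
        if not self.sessions:
            raise CalendarError("empty calendar")
        doses = {s.dose for s in self.sessions}
        if len(doses) > 1:
            raise ConsistencyError(
                "calendar mixes doses per fraction; summarize segments separately"
            )
        return ScheduleSummary(
            N=self.n_fractions,
            d=doses.pop(),
            T=overall_time(self),
            TD=len(self.twice_daily_days),
            m=m_hours,
        )


def overall_time(calendar: TreatmentCalendar) -> int:
    """Overall treatment time in calendar days, inclusive of both ends."""
    if not calendar.sessions:
        raise CalendarError("empty calendar")
    first = calendar.sessions[0].date
    last = calendar.sessions[-1].date
    return (last - first).days + 1


def validate_schedule(calendar: TreatmentCalendar) -> list[str]:
    """Return human-readable violations of the gap-compensation constraints.

    Checks: more than 6 fractions in any ISO (Mon-Sun) week; twice-daily
    days on consecutive calendar days; same-day sessions under 6 h apart.
    Never raises, never mutates.
    """
    violations: list[str] = []
    weeks: dict[tuple[int, int], int] = {}
    for s in calendar.sessions:
        iso = s.date.isocalendar()
        weeks[(iso[0], iso[1])] = weeks.get((iso[0], iso[1]), 0) + 1
    for (year, week), count in sorted(weeks.items()):
        if count > MAX_FRACTIONS_PER_WEEK:
            violations.append(
                f"week {year}-W{week:02d}: {count} fractions exceeds "
                f"{MAX_FRACTIONS_PER_WEEK}/week"
            )
    bid = calendar.twice_daily_days
    for a, b in zip(bid, bid[1:]):
        if (b - a).days == 1:
            violations.append(f"twice-daily fractionation on consecutive days {a} and {b}")
    by_day: dict[dt.date, list[TreatmentSession]] = {}
    for s in calendar.sessions:
        by_day.setdefault(s.date, []).append(s)
    for date, sessions in sorted(by_day.items()):
        if len(sessions) == 2:
            gap_h = (sessions[1].when - sessions[0].when).total_seconds() / 3600.0
            if gap_h < MIN_INTERVAL_H:
                violations.append(
                    f"{date}: interfraction interval {gap_h:.1f} h below "
                    f"{MIN_INTERVAL_H:g} h"
                )
    return violations


def build_calendar(
    start: dt.date,
    n_fractions: int,
    dose_per_fraction: float,
    *,
    treatment_days_per_week: int = 5,
    bid_days: int = 0,
    interval_hours: float = MIN_INTERVAL_H,
    skip: Sequence[dt.date] = (),
) -> TreatmentCalendar:
    """Lay out sessions on consecutive treatment days.

    Fractions fill Monday-Friday (or Monday-Saturday with
    ``treatment_days_per_week = 6``), skipping any ``skip`` dates (e.g. a
    gap).  ``bid_days`` treatment days get two sessions, placed on
    alternating treatment days from the start so no two twice-daily days are
    consecutive.
    """
    if n_fractions < 1:
        raise InvalidParameterError("n_fractions must be >= 1")
    if treatment_days_per_week not in (5, 6, 7):
        raise InvalidParameterError("treatment_days_per_week must be 5, 6, or 7")
    if bid_days * 2 > n_fractions:
        raise InvalidParameterError("bid_days cannot exceed n_fractions / 2")
    am = dt.time(9, 0)
    pm_minutes = int(round(interval_hours * 60))
    pm = (dt.datetime.combine(start, am) + dt.timedelta(minutes=pm_minutes)).time()
    skip_set = set(skip)
    sessions: list[TreatmentSession] = []
    week_counts: dict[tuple[int, int], int] = {}
    remaining = n_fractions
    bid_remaining = bid_days
    day = start
    last_was_bid = False
    while remaining > 0:
        iso = day.isocalendar()
        week = (iso[0], iso[1])
        in_week = week_counts.get(week, 0)
        weekday_ok = day.weekday() < treatment_days_per_week
        if weekday_ok and day not in skip_set and in_week < MAX_FRACTIONS_PER_WEEK:
            take_bid = (
                bid_remaining > 0 and not last_was_bid and remaining >= 2
                and in_week + 2 <= MAX_FRACTIONS_PER_WEEK
            )
            sessions.append(TreatmentSession(day, am, dose_per_fraction))
            remaining -= 1
            week_counts[week] = week_counts.get(week, 0) + 1
            if take_bid:
                sessions.append(TreatmentSession(day, pm, dose_per_fraction))
                remaining -= 1
                bid_remaining -= 1
                week_counts[week] += 1
            last_was_bid = take_bid
        else:
            last_was_bid = False
        day += dt.timedelta(days=1)
    return TreatmentCalendar(tuple(sessions))


# ---------------------------------------------------------------------------
# plan evaluation

@dataclass(frozen=True)
class PlanSegment:
    """A contiguous block of fractions with one dose per fraction.

    ``t_end`` is the cumulative overall treatment time (calendar days from
    the start of the whole course) at the segment's end.
    """

    label: str
    n: int
    d: float
    t_end: float
    td: int = 0
    m_hours: float = MIN_INTERVAL_H

    @property
    def total_dose(self) -> float:
        return self.n * self.d

    def schedule(self) -> ScheduleSummary:
        return ScheduleSummary(N=self.n, d=self.d, T=self.t_end,
                               TD=self.td, m=self.m_hours)


@dataclass(frozen=True)
class PlanRow:
    """One accounting row: a segment or the whole-course total."""

    label: str
    physical_dose: float
    d: float
    n: int
    t: float
    bed: float  # Gy_{alpha/beta}, repopulation-corrected
    eqd2: float
    dose_lost: float  # cumulative repopulation loss at this row's T

    def rounded(self) -> "PlanRow":
        return PlanRow(
            label=self.label,
            physical_dose=round_report(self.physical_dose),
            d=self.d,
            n=self.n,
            t=self.t,
            bed=round_report(self.bed),
            eqd2=round_report(self.eqd2),
            dose_lost=round_report(self.dose_lost),
        )


@dataclass(frozen=True)
class PlanEvaluation:
    """Segment rows plus the whole-course total for one plan."""

    label: str
    params_name: str
    alpha_beta: float
    rows: tuple[PlanRow, ...]
    total: PlanRow
    headline: Optional[dict[str, float]] = None  # DVH-mode statistics
    dvh: Optional[DVH] = None  # EQD2 DVH in DVH mode

    def difference(self, other: "PlanEvaluation") -> dict[str, float]:
        """Intended-minus-this differences of the 1-decimal rounded totals."""
        return {
            "bed": round_report(
                round_report(other.total.bed) - round_report(self.total.bed)
            ),
            "eqd2": round_report(
                round_report(other.total.eqd2) - round_report(self.total.eqd2)
            ),
        }


def bid_session_groups(
    n: int, td: int, params: TissueParams, m_hours: float
) -> list[tuple[int, float]]:
    """Split N fractions into (count, h) groups for TD twice-daily days.

    Tumors repair fully within the recommended >= 6 h interval, so h = 0 for
    every tumor fraction; OAR fractions on twice-daily days carry the
    incomplete-repair factor for the structure's repair half-time.
    """
    if td == 0 or params.tissue_class == "tumor":
        return [(n, 0.0)]
    h = incomplete_repair_factor(params.repair_half_time, m_hours)
    n_bid = 2 * td
    if n_bid > n:
        raise ConsistencyError("twice-daily fractions exceed total fractions")
    return [(n_bid, h), (n - n_bid, 0.0)]


def evaluate_plan(
    segments: Sequence[PlanSegment],
    params: TissueParams,
    dvh: Optional[DVH] = None,
    label: str = "plan",
    reference_dose: Optional[float] = None,
) -> PlanEvaluation:
    """Evaluate a course of contiguous segments against the LQ model.

    Scalar mode (``dvh=None``) reproduces the segment-accounting table rows:
    each segment's BED carries the repopulation loss accrued between the
    previous segment's end and its own (cumulative attribution), EQD2 is the
    BED scaled by the tissue's factor, and the "dose lost" column is the
    cumulative loss at each row's overall time.

    DVH mode additionally converts ``dvh`` (a physical-dose DVH of the
    *intended* course when ``reference_dose`` is its prescription dose, or of
    the delivered course directly) into a repopulation-corrected EQD2 DVH for
    the delivered course and reports its headline statistics.  The dose axis
    is scaled by delivered/reference total dose, i.e. the revised course is
    assumed to deliver the same normalized dose distribution.
    """
    if not segments:
        raise CalendarError("a plan needs at least one segment")
    t_ends = [s.t_end for s in segments]
    if any(b <= a for a, b in zip(t_ends, t_ends[1:])):
        raise CalendarError("segments must be ordered and non-overlapping in time")

    rows: list[PlanRow] = []
    prior_loss = 0.0
    total_bed = 0.0
    for seg in segments:
        h_groups = bid_session_groups(seg.n, seg.td, params, seg.m_hours)
        # per-segment scalar BED: apportion the LQ term over session groups
        sched = seg.schedule()
        lq = sum(
            seg.total_dose * (n_g / seg.n)
            * (1.0 + seg.d * (1.0 + h_g) / params.alpha_beta)
            for n_g, h_g in h_groups
        )
        loss_end = repopulation_loss(params, seg.t_end)
        bed = lq - (loss_end - prior_loss)
        rows.append(
            PlanRow(
                label=seg.label,
                physical_dose=seg.total_dose,
                d=seg.d,
                n=seg.n,
                t=seg.t_end,
                bed=bed,
                eqd2=bed * params.eqd2_factor,
                dose_lost=loss_end,
            )
        )
        prior_loss = loss_end
        total_bed += bed

    last = segments[-1]
    total = PlanRow(
        label=label,
        physical_dose=sum(s.total_dose for s in segments),
        d=last.d,
        n=sum(s.n for s in segments),
        t=last.t_end,
        bed=total_bed,
        eqd2=total_bed * params.eqd2_factor,
        dose_lost=prior_loss,
    )

    headline = None
    out_dvh = None
    if dvh is not None:
        delivered = sum(s.total_dose for s in segments)
        scaled = dvh
        if reference_dose is not None and reference_dose > 0:
            scaled = scale_dvh_dose(dvh, delivered / reference_dose)
        n_total = sum(s.n for s in segments)
        td_total = sum(s.td for s in segments)
        m_hours = segments[-1].m_hours
        d_eff = delivered / n_total
        schedule = ScheduleSummary(
            N=n_total, d=d_eff, T=last.t_end, TD=td_total, m=m_hours
        )
        groups = bid_session_groups(n_total, td_total, params, m_hours)
        out_dvh = convert_dvh(scaled, schedule, params, groups)
        headline = {
            "D98%": dvh_statistic(out_dvh, "D_x%", 98.0),
            "D2%": dvh_statistic(out_dvh, "D_x%", 2.0),
            "Dmean": dvh_statistic(out_dvh, "Dmean"),
            "Dmax": dvh_statistic(out_dvh, "Dmax"),
        }

    return PlanEvaluation(
        label=label,
        params_name=params.name,
        alpha_beta=params.alpha_beta,
        rows=tuple(rows),
        total=total,
        headline=headline,
        dvh=out_dvh,
    )


def point_dose_rcr(
    prescription_dose_per_fraction: float,
    schedule: ScheduleSummary,
    params: TissueParams,
    h: float = 0.0,
) -> dict[str, float]:
    """The 1-D point-dose gap calculation: the whole structure at one dose.

    Returns the BED and EQD2 of ``N`` fractions of the single representative
    dose per fraction.  Kept alongside the DVH method to expose how a
    worst-case point dose overestimates the dose to a non-uniform OAR.
    """
    d = prescription_dose_per_fraction
    sched = replace(schedule, d=d)
    bed = bed_scalar(sched.N * d, sched, params, h)
    return {"bed": bed.value, "eqd2": eqd2_from_bed(bed, params)}


def scale_dvh_dose(dvh: DVH, factor: float) -> DVH:
    """Scale a DVH's dose axis (volumes unchanged)."""
    if factor <= 0:
        raise InvalidParameterError("dose scale factor must be positive")
    return replace(
        dvh,
        bin_edges=dvh.bin_edges * factor,
        bin_doses=None if dvh.bin_doses is None else dvh.bin_doses * factor,
    )
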