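"""Traffic-light exacerbation-detection state machine.

Implements the monitoring rules of a COPD action-plan app: a daily yes/no
symptom question (BASE) drives a green -> yellow -> orange escalation, an
on-demand severity question (PLUS) can jump straight to orange or red, and
a step counter compared against a personal goal adds an activity pathway
(20% decline -> orange, 40% -> red).  The patient's overall zone is the
worst of the symptom and activity components, and an informal caregiver
("buddy") is alerted on every overall-zone change.

Zone semantics:

* GREEN  - steady state.
* YELLOW - symptoms worsened; read the personal exacerbation plan and
  adapt medication.
* ORANGE - no improvement for 3 consecutive days, an orange-class PLUS
  answer, or a 20% step decline; take emergency medication or contact a
  health care professional.
* RED    - a life-threatening PLUS answer (buddy advised to call an
  ambulance) or a 40% step decline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .cohort import DailyRecord

__all__ = [
    "Zone",
    "PlusAnswer",
    "ZoneState",
    "AlertEvent",
    "Advice",
    "SequencingError",
    "init_state",
    "process_base",
    "process_plus",
    "assess_step_baseline",
    "step_zone_of",
    "ccq_due",
    "replay",
]

#: length of the activity baseline assessment, days (3 weeks)
BASELINE_DAYS = 21
#: consecutive worse days that escalate the symptom pathway to ORANGE
ESCALATION_DAYS = 3
#: fractional step declines relative to the goal
ORANGE_DECLINE = 0.20
RED_DECLINE = 0.40


class SequencingError(ValueError):
    """Raised when daily inputs arrive out of day order."""


class Zone(enum.IntEnum):
    """Ordered monitoring zones, mildest to most severe."""

    GREEN = 0
    YELLOW = 1
    ORANGE = 2
    RED = 3


class Advice(str, enum.Enum):
    NONE = "NONE"
    READ_PLAN_ADAPT_MEDICATION = "READ_PLAN_ADAPT_MEDICATION"
    EMERGENCY_MEDICATION_OR_CONTACT_HCP = "EMERGENCY_MEDICATION_OR_CONTACT_HCP"
    CALL_AMBULANCE = "CALL_AMBULANCE"


class PlusAnswer(str, enum.Enum):
    """On-demand severity question answers and their mapped zone class."""

    HEMOPTYSIS = "HEMOPTYSIS"
    FEVER = "FEVER"
    TOO_SICK_FOR_ACTIVITIES = "TOO_SICK_FOR_ACTIVITIES"
    VERY_DYSPNEIC = "VERY_DYSPNEIC"
    CHEST_PAIN = "CHEST_PAIN"
    CONFUSED = "CONFUSED"
    FORGETFULNESS = "FORGETFULNESS"
    DIZZINESS = "DIZZINESS"
    COLLAPSE_TENDENCY = "COLLAPSE_TENDENCY"
    LOSS_OF_CONSCIOUSNESS = "LOSS_OF_CONSCIOUSNESS"
    NONE = "NONE"

    @property
    def mapped_zone(self) -> Zone | None:
        """Zone floor implied by this answer (None = no change)."""
        if self in _PLUS_ORANGE:
            return Zone.ORANGE
        if self in _PLUS_RED:
            return Zone.RED
        return None


_PLUS_ORANGE = frozenset(
    {PlusAnswer.HEMOPTYSIS, PlusAnswer.FEVER, PlusAnswer.TOO_SICK_FOR_ACTIVITIES}
)
_PLUS_RED = frozenset(
    {
        PlusAnswer.VERY_DYSPNEIC,
        PlusAnswer.CHEST_PAIN,
        PlusAnswer.CONFUSED,
        PlusAnswer.FORGETFULNESS,
        PlusAnswer.DIZZINESS,
        PlusAnswer.COLLAPSE_TENDENCY,
        PlusAnswer.LOSS_OF_CONSCIOUSNESS,
    }
)


@dataclass(frozen=True)
class ZoneState:
    """Current state of one patient's monitoring.

    ``overall_zone`` is always the max of the symptom and step components.
    ``red_via_plus`` records whether a current RED symptom zone was reached
    through the PLUS pathway (which alone carries the ambulance advice).
    """

    symptom_zone: Zone = Zone.GREEN
    step_zone: Zone = Zone.GREEN
    overall_zone: Zone = Zone.GREEN
    consecutive_worse_days: int = 0
    step_goal: float | None = None
    baseline_steps: float | None = None
    day_index: int = -1
    red_via_plus: bool = False


@dataclass(frozen=True)
class AlertEvent:
    patient_id: int
    day: int
    from_zone: Zone
    to_zone: Zone
    recipient: str  # "patient" or "buddy"
    advice: Advice


def init_state() -> ZoneState:
    """Fresh state: all zones green (steady state), counters zero, no goal."""
    return ZoneState()


def _advice_for(state: ZoneState, to_zone: Zone) -> Advice:
    if to_zone == Zone.GREEN:
        return Advice.NONE
    if to_zone == Zone.YELLOW:
        return Advice.READ_PLAN_ADAPT_MEDICATION
    if to_zone == Zone.RED and state.red_via_plus:
        return Advice.CALL_AMBULANCE
    # ORANGE, and RED reached through the step pathway
    return Advice.EMERGENCY_MEDICATION_OR_CONTACT_HCP


def _with_overall(state: ZoneState) -> ZoneState:
    return replace(state, overall_zone=max(state.symptom_zone, state.step_zone))


def _emit_alerts(
    old: ZoneState, new: ZoneState, patient_id: int, day: int
) -> list[AlertEvent]:
    """One buddy signal per overall-zone change, carrying the zone's advice.

    The advice code doubles as the in-app guidance the patient sees; the
    caregiver is the alert recipient ("the buddy received a signal when
    the status changed to another color").
    """
    if new.overall_zone == old.overall_zone:
        return []
    return [
        AlertEvent(
            patient_id=patient_id,
            day=day,
            from_zone=old.overall_zone,
            to_zone=new.overall_zone,
            recipient="buddy",
            advice=_advice_for(new, new.overall_zone),
        )
    ]


def _advance_day(state: ZoneState, day: int | None) -> ZoneState:
    if day is None:
        return state
    if day <= state.day_index:
        raise SequencingError(
            f"day {day} not after previous day {state.day_index}"
        )
    return replace(state, day_index=day)


def _apply_base(state: ZoneState, worse: bool) -> ZoneState:
    """Symptom-pathway update for one answered BASE question.

    Improvement (worse=False) returns the symptom zone to GREEN and
    resets the counter; worsening escalates GREEN->YELLOW immediately and
    YELLOW->ORANGE after 3 consecutive worse days.  Unanswered days do
    not call this function: the counter freezes, since absence of an
    answer is not evidence of improvement.
    """
    if not worse:
        return replace(
            state, symptom_zone=Zone.GREEN, consecutive_worse_days=0, red_via_plus=False
        )
    count = state.consecutive_worse_days + 1
    zone = state.symptom_zone
    if zone == Zone.GREEN:
        zone = Zone.YELLOW
    if count >= ESCALATION_DAYS and zone < Zone.ORANGE:
        zone = Zone.ORANGE
    return replace(state, symptom_zone=zone, consecutive_worse_days=count)


def _apply_plus(state: ZoneState, answer: PlusAnswer) -> ZoneState:
    """PLUS answers raise the symptom zone to a floor, never lower it."""
    if not isinstance(answer, PlusAnswer):
        try:
            answer = PlusAnswer(answer)
        except ValueError:
            raise ValueError(f"unknown PLUS answer {answer!r}") from None
    floor = answer.mapped_zone
    if floor is None or floor <= state.symptom_zone:
        return state
    return replace(
        state, symptom_zone=floor, red_via_plus=(floor == Zone.RED)
    )


def process_base(
    state: ZoneState, worse: bool, day: int | None = None
) -> tuple[ZoneState, list[AlertEvent]]:
    """Apply one answered daily BASE question; returns new state and alerts."""
    state = _advance_day(state, day)
    new = _with_overall(_apply_base(state, worse))
    return new, _emit_alerts(state, new, patient_id=0, day=new.day_index)


def process_plus(
    state: ZoneState, answer: PlusAnswer, day: int | None = None
) -> tuple[ZoneState, list[AlertEvent]]:
    """Apply one on-demand PLUS answer; returns new state and alerts."""
    state = _advance_day(state, day)
    new = _with_overall(_apply_plus(state, answer))
    return new, _emit_alerts(state, new, patient_id=0, day=new.day_index)


def assess_step_baseline(first_days: Sequence[float | None]) -> float | None:
    """Mean daily steps over the 3-week baseline window.

    Expects exactly 21 values (missing days as None); returns None when
    every day is missing, in which case step monitoring stays disabled.
    """
    if len(first_days) != BASELINE_DAYS:
        raise ValueError(
            f"baseline assessment needs exactly {BASELINE_DAYS} daily values, "
            f"got {len(first_days)}"
        )
    present = [v for v in first_days if v is not None]
    if not present:
        return None
    return float(sum(present)) / len(present)


def step_zone_of(steps: float, goal: float | None) -> Zone:
    """Zone implied by today's steps relative to the personal goal.

    Ties go to the more severe zone: exactly 20% (40%) below the goal
    already counts as ORANGE (RED).  Between 80% and 100% of the goal the
    patient stays GREEN - there is no yellow activity zone.
    """
    if goal is None:
        raise ValueError(
            "step goal is unset; assess the 3-week step baseline first"
        )
    if goal <= 0:
        raise ValueError("step goal must be > 0")
    if steps <= (1.0 - RED_DECLINE) * goal:
        return Zone.RED
    if steps <= (1.0 - ORANGE_DECLINE) * goal:
        return Zone.ORANGE
    return Zone.GREEN


def ccq_due(day: int) -> bool:
    """Whether the health-status questionnaire is scheduled on this day.

    Three times a week, anchored at inclusion: days 0, 2 and 4 of each
    7-day cycle.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    return day % 7 in (0, 2, 4)


def replay(
    records: Iterable[DailyRecord], goal_factor: float = 1.0
) -> tuple[list[tuple[int, Zone]], list[AlertEvent]]:
    """Run the full rule set over one patient's day-ordered log.

    Days 0-20 form the activity baseline; afterwards the step goal is
    ``goal_factor`` times the baseline mean and the activity pathway is
    active (the step zone persists between step observations).  Each day
    the BASE answer (if any), PLUS answer (if any) and step count (if
    any) are applied; the end-of-day overall zone is the max of the two
    components, and exactly one buddy alert is emitted per change of the
    end-of-day overall zone.

    Returns the per-day ``(day, overall_zone)`` series and the alert log
    (patient advice alerts plus buddy change alerts).
    """
    records = list(records)
    if not records:
        return [], []
    days = [r.day for r in records]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise SequencingError("daily records must be sorted by strictly increasing day")

    patient_id = records[0].patient_id
    baseline_window: list[float | None] = [None] * BASELINE_DAYS
    state = init_state()
    series: list[tuple[int, Zone]] = []
    alerts: list[AlertEvent] = []

    for rec in records:
        if rec.patient_id != patient_id:
            raise ValueError("replay expects records from a single patient")
        state = replace(state, day_index=rec.day)
        if rec.day < BASELINE_DAYS:
            if rec.steps is not None:
                baseline_window[rec.day] = rec.steps
        elif state.baseline_steps is None and state.step_goal is None:
            base = assess_step_baseline(baseline_window)
            if base is not None:
                state = replace(
                    state, baseline_steps=base, step_goal=goal_factor * base
                )

        before = state
        if rec.base_answered:
            state = _apply_base(state, bool(rec.base_worse))
        if rec.plus_answer is not None:
            state = _apply_plus(state, PlusAnswer(rec.plus_answer))
        if (
            rec.steps is not None
            and rec.day >= BASELINE_DAYS
            and state.step_goal is not None
        ):
            state = replace(state, step_zone=step_zone_of(rec.steps, state.step_goal))
        state = _with_overall(state)
        day_alerts = _emit_alerts(before, state, patient_id=patient_id, day=rec.day)
        alerts.extend(day_alerts)
        series.append((rec.day, state.overall_zone))

    return series, alerts
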