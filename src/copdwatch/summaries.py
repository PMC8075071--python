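"""Per-patient usage summaries and cohort descriptive statistics.

Reduces a patient's daily monitoring log and replayed zone series to the
counts a telemonitoring evaluation reports: questionnaires answered,
symptomatic answers, on-demand answers by mapped zone class, days spent
in the orange and red zones, and median daily steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import DailyRecord
from .zones import PlusAnswer, Zone

__all__ = ["UsageSummary", "DescriptiveStats", "summarize_usage", "describe"]


@dataclass(frozen=True)
class UsageSummary:
    patient_id: int
    n_base_answered: int
    n_base_yes: int
    n_plus_answered: int
    n_plus_orange: int
    n_plus_red: int
    days_in_orange: int
    days_in_red: int
    median_steps: float | None


@dataclass(frozen=True)
class DescriptiveStats:
    """Median / quartiles (linear interpolation) plus mean and SD."""

    median: float
    iqr: tuple[float, float]
    mean: float
    sd: float


def summarize_usage(
    records: Sequence[DailyRecord],
    zone_series: Sequence[tuple[int, Zone]],
) -> UsageSummary:
    """Summarize one patient's log against its replayed zone series.

    ``zone_series`` must come from :func:`copdwatch.zones.replay` on the
    same records; "days in orange/red" count days whose end-of-day
    overall zone is ORANGE/RED.
    """
    ids = {r.patient_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix patient ids {sorted(ids)}")
    if len(zone_series) != len(records):
        raise ValueError(
            "zone series and records disagree in length; replay the same log"
        )
    pid = ids.pop() if ids else 0

    n_answered = sum(r.base_answered for r in records)
    n_yes = sum(bool(r.base_worse) for r in records)
    plus = [PlusAnswer(r.plus_answer) for r in records if r.plus_answer is not None]
    zones = [z for _, z in zone_series]
    steps = [r.steps for r in records if r.steps is not None]
    return UsageSummary(
        patient_id=pid,
        n_base_answered=int(n_answered),
        n_base_yes=int(n_yes),
        n_plus_answered=len(plus),
        n_plus_orange=sum(a.mapped_zone == Zone.ORANGE for a in plus),
        n_plus_red=sum(a.mapped_zone == Zone.RED for a in plus),
        days_in_orange=sum(z == Zone.ORANGE for z in zones),
        days_in_red=sum(z == Zone.RED for z in zones),
        median_steps=float(np.median(steps)) if steps else None,
    )


def describe(values: Iterable[float]) -> DescriptiveStats:
    """Median, IQR (linear-interpolation quartiles), mean and sample SD.

    SD uses the n-1 denominator and is NaN for a single observation.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("describe needs at least one value")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return DescriptiveStats(
        median=float(med), iqr=(float(q1), float(q3)), mean=float(arr.mean()), sd=sd
    )
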