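"""Non-homogeneous Poisson patient arrivals and hours classification.

Arrivals follow a piecewise-constant-rate Poisson process over twelve two-hour clock
blocks (00–02, 02–04, …, 22–24), identical for every day of the week; day-of-week
structure in the data enters only through the regular/out-of-hours split. The block
rates are arrivals per hour; within each block the count is Poisson with mean
``rate * 2 * scale`` and event times are uniform.

Regular hours are Monday–Friday 08:00–16:00 (half-open on the right: 16:00 exactly is
out of hours); everything else, including all of Saturday and Sunday, is out of hours.
The simulated horizon starts at Monday 00:00 and a year is 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ArrivalSchedule",
    "generate_arrivals",
    "classify_hours",
    "assign_pathway",
    "expected_regular_fraction",
    "MINUTES_PER_DAY",
    "MINUTES_PER_WEEK",
    "REGULAR_START_MIN",
    "REGULAR_END_MIN",
]

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY
REGULAR_START_MIN = 8 * 60
REGULAR_END_MIN = 16 * 60
N_BLOCKS = 12
BLOCK_MINUTES = 120


@dataclass(frozen=True)
class ArrivalSchedule:
    """Twelve two-hour block rates (arrivals/hour) plus a site volume multiplier."""

    block_rates: tuple[float, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_rates",
                           tuple(float(r) for r in self.block_rates))

    def validate(self) -> list[str]:
        problems = []
        if len(self.block_rates) != N_BLOCKS:
            problems.append(
                f"schedule needs {N_BLOCKS} block rates, got {len(self.block_rates)}")
        if any(r < 0 for r in self.block_rates):
            problems.append("block rates must be non-negative")
        if not any(r > 0 for r in self.block_rates):
            problems.append("at least one block rate must be positive")
        if self.scale <= 0:
            problems.append("arrival scale must be > 0")
        return problems

    def scaled(self, k: float) -> "ArrivalSchedule":
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        return replace(self, scale=self.scale * k)

    def expected_per_day(self) -> float:
        return sum(self.block_rates) * 2.0 * self.scale


def generate_arrivals(schedule: ArrivalSchedule, horizon_days: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Sorted arrival times in minutes from the horizon start (Monday 00:00)."""
    problems = schedule.validate()
    if problems:
        raise ValueError("; ".join(problems))
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    lam = np.array(schedule.block_rates) * 2.0 * schedule.scale
    counts = rng.poisson(lam, size=(horizon_days, N_BLOCKS))
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    day_idx, block_idx = np.nonzero(counts)
    reps = counts[day_idx, block_idx]
    day_idx = np.repeat(day_idx, reps)
    block_idx = np.repeat(block_idx, reps)
    offsets = rng.random(total) * BLOCK_MINUTES
    times = day_idx * MINUTES_PER_DAY + block_idx * BLOCK_MINUTES + offsets
    times.sort()
    return times


def classify_hours(t: float) -> str:
    """``"regular"`` iff t falls on Monday–Friday in [08:00, 16:00), else out of hours."""
    if t < 0:
        raise ValueError("time must be >= 0")
    minute_of_week = t % MINUTES_PER_WEEK
    day = int(minute_of_week // MINUTES_PER_DAY)  # 0 = Monday
    minute_of_day = minute_of_week % MINUTES_PER_DAY
    if day < 5 and REGULAR_START_MIN <= minute_of_day < REGULAR_END_MIN:
        return "regular"
    return "out_of_hours"


def assign_pathway(rng: np.random.Generator, p_ems: float) -> str:
    """Bernoulli pathway assignment, independent across patients."""
    if not 0.0 <= p_ems <= 1.0:
        raise ValueError("p_ems must be in [0, 1]")
    return "EMS" if rng.random() < p_ems else "PV"


def expected_regular_fraction(schedule: ArrivalSchedule) -> float:
    """Analytic fraction of arrivals in regular hours.

    Blocks 08–10 through 14–16 cover the regular-hours window; with rates identical
    across days of week, the weekday structure contributes an exact factor 5/7.
    """
    total = sum(schedule.block_rates)
    if total <= 0:
        raise ValueError("schedule has no positive rate")
    props = [r / total for r in schedule.block_rates]
    return sum(props[4:8]) * 5.0 / 7.0
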