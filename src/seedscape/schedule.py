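"""Germination trial containers and CSV ingestion.

A trial is scored as a *schedule*: for one Petri dish of ``total_seeds``
achenes checked daily over ``duration_days``, ``daily_counts[i]`` is the
number of seeds whose radicle first reached 1 mm on day ``i + 1``.  All
time-to-event indices are computed from this vector, so validation is
strict: counts must be non-negative integers and can never exceed the
number of seeds sown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GerminationSchedule",
    "CutTestSummary",
    "ScheduleValidationError",
    "schedule_from_events",
    "read_schedules",
    "read_cut_tests",
    "schedules_to_frame",
]


class ScheduleValidationError(ValueError):
    """Raised when a germination schedule violates its invariants."""


@dataclass(frozen=True)
class GerminationSchedule:
    """Daily new-germination counts for one dish.

    Parameters
    ----------
    dish_id, treatment_id
        Identifiers carried through to output tables.
    total_seeds
        Number of seeds sown in the dish (N).
    duration_days
        Trial length in days (k); the dish was checked every 24 h.
    daily_counts
        Length-k sequence; element ``i`` is the number of seeds newly
        germinated on day ``i + 1``.
    """

    dish_id: str
    treatment_id: str
    total_seeds: int
    duration_days: int
    daily_counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "daily_counts", tuple(int(c) for c in self.daily_counts))
        self.validate()

    def validate(self) -> None:
        if self.total_seeds <= 0:
            raise ScheduleValidationError(
                f"dish {self.dish_id!r}: total_seeds must be positive, got {self.total_seeds}"
            )
        if self.duration_days <= 0:
            raise ScheduleValidationError(
                f"dish {self.dish_id!r}: duration_days must be positive, got {self.duration_days}"
            )
        if len(self.daily_counts) != self.duration_days:
            raise ScheduleValidationError(
                f"dish {self.dish_id!r}: daily_counts has length {len(self.daily_counts)}, "
                f"expected duration_days={self.duration_days}"
            )
        for day, c in enumerate(self.daily_counts, start=1):
            if c < 0:
                raise ScheduleValidationError(
                    f"dish {self.dish_id!r}: negative count {c} on day {day}"
                )
        if self.total_germinated > self.total_seeds:
            raise ScheduleValidationError(
                f"dish {self.dish_id!r}: {self.total_germinated} germinations exceed "
                f"{self.total_seeds} seeds sown"
            )

    @property
    def total_germinated(self) -> int:
        return sum(self.daily_counts)

    @property
    def event_days(self) -> tuple[int, ...]:
        """Days (1-based) on which at least one seed germinated."""
        return tuple(d for d, c in enumerate(self.daily_counts, start=1) if c > 0)

    def events(self) -> dict[int, int]:
        """Sparse ``{day: count}`` view of the non-zero daily counts."""
        return {d: c for d, c in enumerate(self.daily_counts, start=1) if c > 0}


def schedule_from_events(
    dish_id: str,
    treatment_id: str,
    total_seeds: int,
    duration_days: int,
    events: Mapping[int, int],
) -> GerminationSchedule:
    """Build a schedule from a sparse ``{day: new germinations}`` mapping."""
    counts = [0] * duration_days
    for day, c in events.items():
        if not 1 <= day <= duration_days:
            raise ScheduleValidationError(
                f"dish {dish_id!r}: event day {day} outside 1..{duration_days}"
            )
        counts[day - 1] += int(c)
    return GerminationSchedule(dish_id, treatment_id, total_seeds, duration_days, tuple(counts))


@dataclass(frozen=True)
class CutTestSummary:
    """End-of-trial cut-test classification of ungerminated seeds.

    Seeds are dissected and scored viable/fresh (white, firm embryo),
    empty (embryoless — common in Apiaceae), or dead.
    """

    dish_id: str
    n_viable: int
    n_empty: int
    n_dead: int

    def __post_init__(self) -> None:
        for name in ("n_viable", "n_empty", "n_dead"):
            v = getattr(self, name)
            if v < 0:
                raise ScheduleValidationError(f"dish {self.dish_id!r}: {name} = {v} < 0")
        if self.n_tested == 0:
            raise ScheduleValidationError(
                f"dish {self.dish_id!r}: cut test with zero seeds tested"
            )

    @property
    def n_tested(self) -> int:
        return self.n_viable + self.n_empty + self.n_dead

    @property
    def pct_viable(self) -> float:
        return 100.0 * self.n_viable / self.n_tested

    @property
    def pct_empty(self) -> float:
        return 100.0 * self.n_empty / self.n_tested

    @property
    def pct_dead(self) -> float:
        return 100.0 * self.n_dead / self.n_tested


def _is_cumulative(counts: Sequence[int], total_seeds: int) -> bool:
    # A full-length non-decreasing series with a repeated positive value is
    # read as cumulative counts; strictly daily data re-hitting the same
    # cumulative value is indistinguishable, hence the explicit flag gate.
    if len(counts) < 2:
        return False
    nondecreasing = all(b >= a for a, b in zip(counts, counts[1:]))
    return nondecreasing and max(counts) > 0 and sum(counts) > total_seeds


def read_schedules(
    schedules_csv,
    dishes_csv,
    allow_cumulative: bool = False,
) -> list[GerminationSchedule]:
    """Read trial schedules from the two-file CSV layout.

    ``dishes.csv`` carries dish_id, treatment_id, total_seeds, duration_days;
    ``schedules.csv`` carries dish_id, treatment_id, day, n_germinated with
    missing days meaning zero.  With ``allow_cumulative`` set, a dish whose
    counts form a non-decreasing series summing past ``total_seeds`` is
    auto-detected as cumulative and differenced; the default reads counts
    strictly as daily increments.
    """
    sched = pd.read_csv(schedules_csv)
    dishes = pd.read_csv(dishes_csv)
    required = {"dish_id", "treatment_id", "day", "n_germinated"}
    if not required.issubset(sched.columns):
        raise ScheduleValidationError(
            f"schedules CSV missing columns: {sorted(required - set(sched.columns))}"
        )
    required_d = {"dish_id", "treatment_id", "total_seeds", "duration_days"}
    if not required_d.issubset(dishes.columns):
        raise ScheduleValidationError(
            f"dishes CSV missing columns: {sorted(required_d - set(dishes.columns))}"
        )

    out: list[GerminationSchedule] = []
    grouped = dict(tuple(sched.groupby("dish_id")))
    for row in dishes.itertuples(index=False):
        k = int(row.duration_days)
        counts = [0] * k
        g = grouped.get(row.dish_id)
        if g is not None:
            for r in g.itertuples(index=False):
                day = int(r.day)
                n = int(r.n_germinated)
                if not 1 <= day <= k:
                    raise ScheduleValidationError(
                        f"dish {row.dish_id!r}: day {day} outside 1..{k}"
                    )
                if n < 0:
                    raise ScheduleValidationError(
                        f"dish {row.dish_id!r}: n_germinated = {n} < 0 on day {day}"
                    )
                counts[day - 1] = n
        if allow_cumulative and _is_cumulative(counts, int(row.total_seeds)):
            counts = [counts[0]] + [b - a for a, b in zip(counts, counts[1:])]
        out.append(
            GerminationSchedule(
                dish_id=str(row.dish_id),
                treatment_id=str(row.treatment_id),
                total_seeds=int(row.total_seeds),
                duration_days=k,
                daily_counts=tuple(counts),
            )
        )
    return out


def read_cut_tests(cut_test_csv) -> list[CutTestSummary]:
    df = pd.read_csv(cut_test_csv)
    required = {"dish_id", "n_viable", "n_empty", "n_dead"}
    if not required.issubset(df.columns):
        raise ScheduleValidationError(
            f"cut-test CSV missing columns: {sorted(required - set(df.columns))}"
        )
    return [
        CutTestSummary(str(r.dish_id), int(r.n_viable), int(r.n_empty), int(r.n_dead))
        for r in df.itertuples(index=False)
    ]


def schedules_to_frame(schedules: Iterable[GerminationSchedule]) -> pd.DataFrame:
    """Long-format frame (dish_id, treatment_id, day, n_germinated), zeros dropped."""
    rows = []
    for s in schedules:
        for day, c in s.events().items():
            rows.append((s.dish_id, s.treatment_id, day, c))
    return pd.DataFrame(rows, columns=["dish_id", "treatment_id", "day", "n_germinated"])
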