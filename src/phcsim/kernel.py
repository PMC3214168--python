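"""Minimal deterministic discrete-event kernel.

The kernel owns the simulation time axis (integer minutes since 00:00 on
Monday of the first simulated week), an event calendar with deterministic
tie-breaking, weekly opening timetables, named seeded random streams, and
the duration-distribution families used by the clinic models.
"""

from __future__ import annotations

import heapq
import math
import zlib
from dataclasses import dataclass
from typing import Any, Iterable, Iterator, Optional, Sequence

import numpy as np

MINUTES_PER_DAY = 24 * 60
DAYS_PER_WEEK = 7
MINUTES_PER_WEEK = MINUTES_PER_DAY * DAYS_PER_WEEK

__all__ = [
    "MINUTES_PER_DAY",
    "DAYS_PER_WEEK",
    "MINUTES_PER_WEEK",
    "CausalityError",
    "SpecificationError",
    "Event",
    "EventCalendar",
    "WeeklyTimetable",
    "DistributionSpec",
    "RandomStream",
    "weekday_of",
    "day_of",
    "round_half_up",
]


class CausalityError(RuntimeError):
    """An event was scheduled before the current simulation clock."""


class SpecificationError(ValueError):
    """A distribution or timetable specification violates its invariants."""


def weekday_of(t: int) -> int:
    """Weekday index of a simulation time, 0 = Monday."""
    return (t // MINUTES_PER_DAY) % DAYS_PER_WEEK


def day_of(t: int) -> int:
    """Calendar-day index (days since simulation origin)."""
    return t // MINUTES_PER_DAY


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Event:
    """Immutable calendar entry.

    ``priority`` breaks ties at equal time (lower first); insertion order
    breaks remaining ties (FIFO among equals).
    """

    time: int
    priority: int
    kind: str
    payload: Any = None


class EventCalendar:
    """Time/priority-ordered event queue with FIFO tie-breaking.

    ``pop`` always returns the event with the minimal
    ``(time, priority, insertion sequence)`` key; pushing an event earlier
    than the last popped time raises :class:`CausalityError`.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[int, int, int, Event]] = []
        self._seq = 0
        self.clock = 0  # time of the most recently popped event

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, event: Event) -> None:
        if event.time < self.clock:
            raise CausalityError(
                f"event {event.kind!r} at t={event.time} scheduled before clock {self.clock}"
            )
        heapq.heappush(self._heap, (event.time, event.priority, self._seq, event))
        self._seq += 1

    def schedule(self, time: int, priority: int, kind: str, payload: Any = None) -> None:
        self.push(Event(time, priority, kind, payload))

    def peek_time(self) -> Optional[int]:
        return self._heap[0][0] if self._heap else None

    def pop(self) -> Event:
        if not self._heap:
            raise IndexError("pop from empty EventCalendar")
        time, _, _, event = heapq.heappop(self._heap)
        self.clock = time
        return event


class WeeklyTimetable:
    """Weekly-periodic opening hours: per weekday, sorted half-open minute
    intervals ``[start, end)`` within the day."""

    __slots__ = ("days",)

    def __init__(self, days: Sequence[Sequence[tuple[int, int]]]):
        if len(days) != DAYS_PER_WEEK:
            raise SpecificationError("timetable needs exactly 7 weekday entries")
        norm: list[tuple[tuple[int, int], ...]] = []
        for d, intervals in enumerate(days):
            ivs = sorted((int(a), int(b)) for a, b in intervals)
            prev_end = -1
            for a, b in ivs:
                if not (0 <= a < b <= MINUTES_PER_DAY):
                    raise SpecificationError(f"bad interval {(a, b)} on weekday {d}")
                if a < prev_end:
                    raise SpecificationError(f"overlapping intervals on weekday {d}")
                prev_end = b
            norm.append(tuple(ivs))
        self.days = tuple(norm)

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "WeeklyTimetable":
        return cls([[] for _ in range(DAYS_PER_WEEK)])

    @classmethod
    def working_days(cls, start_min: int = 8 * 60, end_min: int = 20 * 60) -> "WeeklyTimetable":
        """Open Monday-Friday within [start, end)."""
        return cls([[(start_min, end_min)] if d < 5 else [] for d in range(DAYS_PER_WEEK)])

    @classmethod
    def full_week(
        cls,
        weekday: tuple[int, int] = (8 * 60, 20 * 60),
        weekend: tuple[int, int] = (10 * 60, 20 * 60),
    ) -> "WeeklyTimetable":
        """Open every day; weekday and weekend hours may differ."""
        return cls([[weekday] if d < 5 else [weekend] for d in range(DAYS_PER_WEEK)])

    @classmethod
    def always_open(cls) -> "WeeklyTimetable":
        return cls([[(0, MINUTES_PER_DAY)] for _ in range(DAYS_PER_WEEK)])

    # -- queries ------------------------------------------------------
    def is_open(self, t: int) -> bool:
        minute = t % MINUTES_PER_DAY
        for a, b in self.days[weekday_of(t)]:
            if a <= minute < b:
                return True
        return False

    def day_windows(self, day: int) -> tuple[tuple[int, int], ...]:
        """Open intervals of a calendar day, as day-local minutes."""
        return self.days[day % DAYS_PER_WEEK]

    def open_minutes(self, weekday: int) -> int:
        return sum(b - a for a, b in self.days[weekday])

    @property
    def weekly_open_minutes(self) -> int:
        return sum(self.open_minutes(d) for d in range(DAYS_PER_WEEK))

    @property
    def open_days_per_week(self) -> int:
        return sum(1 for d in range(DAYS_PER_WEEK) if self.days[d])

    def next_open(self, t: int) -> int:
        """Earliest open minute >= t; raises if the timetable is empty."""
        if self.weekly_open_minutes == 0:
            raise SpecificationError("timetable is never open")
        for offset_day in range(DAYS_PER_WEEK + 1):
            day = day_of(t) + offset_day
            day_start = day * MINUTES_PER_DAY
            minute = t - day_start if offset_day == 0 else 0
            for a, b in self.days[day % DAYS_PER_WEEK]:
                if minute < b:
                    return day_start + max(a, minute)
        raise AssertionError("unreachable: non-empty timetable")

    def iter_open_intervals(self, start: int, end: int) -> Iterator[tuple[int, int]]:
        """Absolute open intervals intersected with [start, end)."""
        day = day_of(start)
        while day * MINUTES_PER_DAY < end:
            base = day * MINUTES_PER_DAY
            for a, b in self.days[day % DAYS_PER_WEEK]:
                lo, hi = max(base + a, start), min(base + b, end)
                if lo < hi:
                    yield (lo, hi)
            day += 1

    def to_dict(self) -> dict[str, list[list[int]]]:
        names = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
        return {names[d]: [list(iv) for iv in self.days[d]] for d in range(DAYS_PER_WEEK)}

    @classmethod
    def from_dict(cls, data: dict) -> "WeeklyTimetable":
        names = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
        return cls([[tuple(iv) for iv in data.get(n, [])] for n in names])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WeeklyTimetable) and self.days == other.days

    def __repr__(self) -> str:
        return f"WeeklyTimetable({self.to_dict()!r})"


_FAMILIES = ("exponential_mean", "lognormal_mean_sd", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Duration/delay distribution in minutes (or days, where so used).

    Families:

    ``fixed(v)``
        degenerate at ``v``.
    ``exponential_mean(m)``
        exponential with mean ``m``.
    ``lognormal_mean_sd(m, s)``
        lognormal parameterized by its *natural-scale* mean ``m`` and
        standard deviation ``s``; the underlying normal has
        ``mu = ln(m^2 / sqrt(m^2 + s^2))`` and ``sigma^2 = ln(1 + s^2/m^2)``.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SpecificationError(f"unknown distribution family {self.family!r}")
        n_expected = {"fixed": 1, "exponential_mean": 1, "lognormal_mean_sd": 2}[self.family]
        if len(self.params) != n_expected:
            raise SpecificationError(
                f"{self.family} takes {n_expected} parameter(s), got {len(self.params)}"
            )
        if any(p <= 0 for p in self.params):
            raise SpecificationError(f"{self.family} parameters must be positive: {self.params}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", (value,))

    @classmethod
    def exponential(cls, mean: float) -> "DistributionSpec":
        return cls("exponential_mean", (mean,))

    @classmethod
    def lognormal(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("lognormal_mean_sd", (mean, sd))

    @property
    def mean(self) -> float:
        return self.params[0]

    @property
    def variance(self) -> float:
        if self.family == "fixed":
            return 0.0
        if self.family == "exponential_mean":
            return self.params[0] ** 2
        return self.params[1] ** 2

    def _lognormal_mu_sigma(self) -> tuple[float, float]:
        m, s = self.params
        sigma2 = math.log(1.0 + (s * s) / (m * m))
        mu = math.log(m * m / math.sqrt(m * m + s * s))
        return mu, math.sqrt(sigma2)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.family == "fixed":
            v = self.params[0]
            return v if size is None else np.full(size, v)
        if self.family == "exponential_mean":
            return rng.exponential(self.params[0], size=size)
        mu, sigma = self._lognormal_mu_sigma()
        return rng.lognormal(mu, sigma, size=size)

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, data: dict) -> "DistributionSpec":
        return cls(data["family"], tuple(data["params"]))


class RandomStream:
    """Named, reproducible random substream.

    Identical ``(seed, label)`` pairs yield identical sample sequences;
    distinct labels decorrelate the streams of one run.
    """

    def __init__(self, seed: int, label: str = "root"):
        self.seed = int(seed)
        self.label = label
        self.rng = np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(label.encode("utf8"))]
        )

    def substream(self, label: str) -> "RandomStream":
        return RandomStream(self.seed, f"{self.label}/{label}")

    def __repr__(self) -> str:
        return f"RandomStream(seed={self.seed}, label={self.label!r})"


def sample_duration(spec: DistributionSpec, stream: RandomStream) -> float:
    """One draw from a duration distribution, in natural-scale minutes."""
    return float(spec.sample(stream.rng))
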