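"""Event calendar ordering, timetables, distribution sampling, seeding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phcsim.kernel import (
    MINUTES_PER_DAY,
    CausalityError,
    DistributionSpec,
    Event,
    EventCalendar,
    RandomStream,
    SpecificationError,
    WeeklyTimetable,
    weekday_of,
)


class TestEventCalendar:
    def test_orders_by_time(self):
        cal = EventCalendar()
        cal.schedule(5, 0, "A")
        cal.schedule(3, 0, "B")
        assert cal.pop().kind == "B"

    def test_priority_breaks_time_ties(self):
        cal = EventCalendar()
        cal.schedule(3, 1, "A")
        cal.schedule(3, 0, "B")
        assert cal.pop().kind == "B"

    def test_fifo_among_equal_keys(self):
        cal = EventCalendar()
        for name in ("first", "second", "third"):
            cal.schedule(7, 2, name)
        assert [cal.pop().kind for _ in range(3)] == ["first", "second", "third"]

    def test_random_events_pop_in_sorted_order(self):
        # oracle: a stable sort of the pushed (time, priority) keys
        rng = np.random.default_rng(42)
        events = [Event(int(t), int(p), f"e{i}") for i, (t, p) in
                  enumerate(zip(rng.integers(0, 500, 1000), rng.integers(0, 3, 1000)))]
        cal = EventCalendar()
        for e in events:
            cal.push(e)
        popped = [cal.pop() for _ in range(len(events))]
        expected = sorted(events, key=lambda e: (e.time, e.priority))
        assert [(e.time, e.priority, e.kind) for e in popped] == [
            (e.time, e.priority, e.kind) for e in expected
        ]

    def test_push_into_past_is_causality_error(self):
        cal = EventCalendar()
        cal.schedule(10, 0, "A")
        cal.pop()
        with pytest.raises(CausalityError):
            cal.schedule(9, 0, "too-late")


class TestWeeklyTimetable:
    def test_phcc_hours(self):
        tt = WeeklyTimetable.full_week()  # working days 8-20, weekend 10-20
        monday_9am = 9 * 60
        assert tt.is_open(monday_9am)
        sunday_9am = 6 * MINUTES_PER_DAY + 9 * 60
        assert not tt.is_open(sunday_9am)  # weekend opens at 10am
        assert tt.is_open(6 * MINUTES_PER_DAY + 10 * 60)

    def test_empty_timetable_never_open(self):
        tt = WeeklyTimetable.empty()
        assert not any(tt.is_open(t) for t in range(0, 7 * MINUTES_PER_DAY, 97))

    def test_next_open_skips_closed_periods(self):
        tt = WeeklyTimetable.working_days()
        friday_9pm = 4 * MINUTES_PER_DAY + 21 * 60
        assert tt.next_open(friday_9pm) == 7 * MINUTES_PER_DAY + 8 * 60  # Monday 8am

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(SpecificationError):
            WeeklyTimetable([[(480, 720), (700, 900)]] + [[]] * 6)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=4 * 7 * MINUTES_PER_DAY))
    def test_next_open_is_open_and_minimal(self, t):
        tt = WeeklyTimetable.full_week()
        t_open = tt.next_open(t)
        assert t_open >= t and tt.is_open(t_open)
        if t_open > t:
            assert not tt.is_open(t_open - 1) or t_open - 1 < t

    def test_weekday_of_origin_is_monday(self):
        assert weekday_of(0) == 0
        assert weekday_of(7 * MINUTES_PER_DAY + 5) == 0


class TestDistributionSpec:
    def test_fixed_is_degenerate(self):
        spec = DistributionSpec.fixed(12)
        rng = np.random.default_rng(0)
        assert all(spec.sample(rng) == 12 for _ in range(10))

    @pytest.mark.parametrize(
        "spec, tol",
        [
            (DistributionSpec.lognormal(15, 5), 0.1),
            (DistributionSpec.exponential(20), 0.5),
        ],
    )
    def test_sampling_mean_matches_closed_form(self, spec, tol):
        rng = np.random.default_rng(1234)
        draws = spec.sample(rng, size=100_000)
        assert abs(draws.mean() - spec.mean) < tol

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec.lognormal(15, 5),
            DistributionSpec.exponential(20),
            DistributionSpec.fixed(7),
        ],
    )
    def test_sampling_moments_within_three_standard_errors(self, spec):
        n = 100_000
        rng = np.random.default_rng(99)
        draws = np.asarray(spec.sample(rng, size=n))
        se_mean = np.sqrt(spec.variance / n) if spec.variance else 0.0
        assert abs(draws.mean() - spec.mean) <= 3 * se_mean + 1e-12
        # variance check via its own sampling error (4th-moment based)
        if spec.variance:
            m4 = np.mean((draws - draws.mean()) ** 4)
            se_var = np.sqrt(max(m4 - spec.variance**2, 0) / n)
            assert abs(draws.var(ddof=1) - spec.variance) <= 4 * se_var

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(SpecificationError):
            DistributionSpec.exponential(0)
        with pytest.raises(SpecificationError):
            DistributionSpec.lognormal(15, -1)

    def test_lognormal_parameterized_by_natural_mean(self):
        # underlying mu/sigma must reproduce the requested natural mean
        spec = DistributionSpec.lognormal(15, 5)
        mu, sigma = spec._lognormal_mu_sigma()
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(15.0)
        assert (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2) == pytest.approx(25.0)


class TestRandomStream:
    def test_same_seed_and_label_reproduce(self):
        a = RandomStream(7, "arrivals").rng.random(5)
        b = RandomStream(7, "arrivals").rng.random(5)
        assert np.array_equal(a, b)

    def test_labels_decorrelate(self):
        a = RandomStream(7, "arrivals").rng.random(5)
        b = RandomStream(7, "durations").rng.random(5)
        assert not np.array_equal(a, b)
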