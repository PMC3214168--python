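"""Clinic model behaviour: booking, arrivals, routing, queue discipline,
re-entry, conservation and determinism."""

import dataclasses
import math

import numpy as np
import pytest

from phcsim.clinic import (
    AppointmentBook,
    CapacityError,
    ModelTypeError,
    Patient,
    book_appointment,
    build_fhu,
    build_model,
    build_phcc,
    generate_arrivals,
    handle_reentry,
)
from phcsim.kernel import (
    MINUTES_PER_DAY,
    MINUTES_PER_WEEK,
    DistributionSpec,
    RandomStream,
    WeeklyTimetable,
)
from phcsim.profiles import ClinicianRoster, CostParameters, UnitProfile
from phcsim.synthetic import generate_unit_profile


def _gp_book(n_gps: int = 1, daily_minutes: int = 420, slot: int = 20) -> AppointmentBook:
    book = AppointmentBook()
    win = WeeklyTimetable.working_days(8 * 60, 8 * 60 + daily_minutes)
    for i in range(n_gps):
        book.register(f"gp{i + 1}", win, slot)
    return book


def _patient(ctype: str = "medical", registered: bool = True, request_time: int = 9 * 60) -> Patient:
    return Patient(1, ctype, registered, "gp1", request_time, "scheduled")


class TestAppointmentBook:
    def test_empty_book_books_next_day(self):
        book = _gp_book()
        pat = _patient()
        cid, day, arrival = book_appointment(book, pat, request_day=0, candidates=["gp1"])
        assert (cid, day) == ("gp1", 1)
        assert pat.days_to_appointment == 1
        assert arrival == 1 * MINUTES_PER_DAY + 8 * 60  # first slot Tuesday 8am

    @pytest.mark.parametrize("full_days", [1, 3, 7])
    def test_first_full_days_skipped(self, full_days):
        # oracle: a linear scan over the per-day free capacities
        book = _gp_book()
        cap = book.capacity("gp1", 1)
        day = 1
        filled = 0
        while filled < full_days:
            if book.capacity("gp1", day) > 0:
                for _ in range(book.capacity("gp1", day)):
                    book.book("gp1", day)
                filled += 1
            day += 1
        free_days = [d for d in range(1, 30)
                     if book.capacity("gp1", d) - book.booked("gp1", d) > 0]
        expected_day = min(free_days)
        cid, booked_day, _ = book_appointment(book, _patient(), 0, ["gp1"])
        assert booked_day == expected_day
        assert book.booked("gp1", booked_day) == 1
        assert cap > 0

    def test_unregistered_patient_takes_earliest_available_gp(self):
        # GP1 full for 5 bookable days, GP2 full for 2: GP2 wins with wait 3
        book = _gp_book(n_gps=2)
        filled = {"gp1": 0, "gp2": 0}
        day = 1
        while filled["gp1"] < 5 or filled["gp2"] < 2:
            for cid, target in (("gp1", 5), ("gp2", 2)):
                if filled[cid] < target and book.capacity(cid, day) > 0:
                    for _ in range(book.capacity(cid, day)):
                        book.book(cid, day)
                    filled[cid] += 1
            day += 1
        pat = Patient(2, "medical", False, None, 9 * 60, "scheduled")
        cid, booked_day, _ = book_appointment(book, pat, 0, ["gp1", "gp2"])
        assert cid == "gp2"
        assert pat.days_to_appointment == 3

    def test_zero_capacity_clinician_is_error(self):
        book = AppointmentBook()
        book.register("gp1", WeeklyTimetable.empty(), 20)
        with pytest.raises(CapacityError):
            book_appointment(book, _patient(), 0, ["gp1"])

    def test_weekend_offers_no_slots(self):
        book = _gp_book()
        assert book.capacity("gp1", 5) == 0 and book.capacity("gp1", 6) == 0


class TestGenerateArrivals:
    def test_poisson_count_oracle(self, small_phcc):
        # rate 60/working-day, all medical, 100 working days = 20 weeks
        prof = dataclasses.replace(
            small_phcc,
            daily_demand_rate=60.0,
            type_profile={"medical": 1.0, "acute": 0.0, "nursing1": 0.0, "nursing2": 0.0},
        )
        arr = generate_arrivals(prof, RandomStream(5), 20 * MINUTES_PER_WEEK)
        assert abs(len(arr) - 6000) <= 3 * math.sqrt(6000)
        assert all(ct == "medical" for _, ct, _ in arr)

    def test_requests_fall_in_open_hours(self, small_phcc):
        arr = generate_arrivals(small_phcc, RandomStream(5), 4 * MINUTES_PER_WEEK)
        sched = small_phcc.scheduled_timetable
        acute = small_phcc.effective_acute_timetable
        for t, ctype, _ in arr:
            tt = acute if ctype == "acute" else sched
            assert tt.is_open(t)

    def test_type_frequencies_match_profile(self, small_phcc):
        prof = dataclasses.replace(small_phcc, daily_demand_rate=500.0)
        arr = generate_arrivals(prof, RandomStream(11), 4 * MINUTES_PER_WEEK)
        n = len(arr)
        assert n > 8000
        for ctype, share in prof.type_profile.items():
            obs = sum(1 for _, ct, _ in arr if ct == ctype) / n
            se = math.sqrt(share * (1 - share) / n)
            assert abs(obs - share) <= 3 * se + 1e-9

    def test_registration_bernoulli(self, small_phcc):
        prof = dataclasses.replace(small_phcc, daily_demand_rate=500.0)
        arr = generate_arrivals(prof, RandomStream(11), 4 * MINUTES_PER_WEEK)
        unreg = sum(1 for _, _, reg in arr if not reg) / len(arr)
        se = math.sqrt(0.1 * 0.9 / len(arr))
        assert abs(unreg - prof.unregistered_fraction) <= 3 * se


class TestReentry:
    def _record(self) -> Patient:
        pat = _patient()
        pat.arrival_time = pat.service_start = 600
        pat.service_end = 615
        return pat

    def test_zero_probability_never_reenters(self, small_phcc):
        prof = dataclasses.replace(small_phcc, reentry_prob=0.0)
        stream = RandomStream(1, "re")
        assert all(handle_reentry(self._record(), prof, stream) is None for _ in range(200))

    def test_certain_reentry_with_fixed_delay(self, small_phcc):
        prof = dataclasses.replace(
            small_phcc, reentry_prob=1.0, reentry_delay_days=DistributionSpec.fixed(7.0)
        )
        t_new, ctype, registered = handle_reentry(self._record(), prof, RandomStream(1, "re"))
        assert t_new == 615 + 7 * MINUTES_PER_DAY
        assert ctype == "medical" and registered

    def test_binomial_reentry_count(self, small_phcc):
        prof = dataclasses.replace(small_phcc, reentry_prob=0.3)
        stream = RandomStream(2, "re")
        n = 10_000
        count = sum(handle_reentry(self._record(), prof, stream) is not None for _ in range(n))
        assert abs(count - 3000) <= 3 * math.sqrt(n * 0.3 * 0.7)


class TestModelBuilders:
    def test_model_type_mismatch_rejected(self, small_phcc, small_fhu):
        with pytest.raises(ModelTypeError):
            build_phcc(small_fhu)
        with pytest.raises(ModelTypeError):
            build_fhu(small_phcc)

    def test_acute_dedicated_gps_take_no_booked_consultations(self, small_phcc):
        log = build_phcc(small_phcc).run(3, 4 * MINUTES_PER_WEEK)
        acute_ids = {r.clinician_id for r in small_phcc.acute_gps}
        assert acute_ids
        for pat in log.served():
            if pat.ctype == "medical":
                assert pat.server_id not in acute_ids
            if pat.ctype == "acute":
                assert pat.server_id in acute_ids

    def test_all_medical_profile_leaves_nursing_streams_empty(self, small_phcc):
        prof = dataclasses.replace(
            small_phcc,
            type_profile={"medical": 1.0, "acute": 0.0, "nursing1": 0.0, "nursing2": 0.0},
        )
        log = build_phcc(prof).run(3, 4 * MINUTES_PER_WEEK)
        assert all(p.ctype == "medical" for p in log.patients)

    def test_zeroing_one_stream_leaves_others_identical(self, small_phcc):
        """Removing acute demand idles the acute facility without touching
        the other streams' trajectories (independent per-type streams)."""
        base = small_phcc
        a = base.type_profile["acute"]
        without = dataclasses.replace(
            base,
            daily_demand_rate=base.daily_demand_rate * (1 - a),
            type_profile={
                "medical": base.type_profile["medical"] / (1 - a),
                "acute": 0.0,
                "nursing1": base.type_profile["nursing1"] / (1 - a),
                "nursing2": base.type_profile["nursing2"] / (1 - a),
            },
        )
        log_a = build_phcc(base).run(9, 3 * MINUTES_PER_WEEK)
        log_b = build_phcc(without).run(9, 3 * MINUTES_PER_WEEK)
        df_a = log_a.to_dataframe().query("type != 'acute'").reset_index(drop=True)
        df_b = log_b.to_dataframe().reset_index(drop=True)
        assert (df_b["type"] != "acute").all()
        cols = ["type", "registered", "request_time", "arrival_time",
                "service_start", "service_end", "server_id"]
        assert df_a[cols].equals(df_b[cols])


class TestQueueDiscipline:
    def _fhu_single_gp(self) -> UnitProfile:
        gp = ClinicianRoster("gp1", "gp", 60.0, 0.0, 20)  # covers the full 12 h day
        nurse = ClinicianRoster("n1", "nurse", 35.0, 21.0, 10)
        return UnitProfile(
            unit_id="fhu-1gp",
            model_type="FHU",
            gps=(gp,),
            nurses=(nurse,),
            n_admin=1,
            timetable=WeeklyTimetable.working_days(),
            acute_timetable=None,
            registered_patients_per_gp=1500,
            unregistered_fraction=0.0,
            daily_demand_rate=18.0,
            type_profile={"medical": 0.6, "acute": 0.4, "nursing1": 0.0, "nursing2": 0.0},
            duration_specs={
                "medical_adult": DistributionSpec.fixed(10.0),
                "medical_other": DistributionSpec.fixed(10.0),
                "acute": DistributionSpec.fixed(5.0),
                "nursing1": DistributionSpec.fixed(20.0),
                "nursing2": DistributionSpec.fixed(10.0),
            },
            reentry_prob=0.0,
            reentry_delay_days=DistributionSpec.fixed(1.0),
            cost_params=CostParameters.fhu_defaults(),
        )

    def test_acute_served_right_after_current_consultation(self):
        """Non-preemptive priority: an acute walk-in arriving while its GP
        is mid-consultation starts exactly when that consultation ends."""
        log = build_fhu(self._fhu_single_gp()).run(21, 4 * MINUTES_PER_WEEK)
        served = sorted(log.served(), key=lambda p: p.service_start)
        checked = 0
        for pat in served:
            if pat.ctype != "acute":
                continue
            blocking = [
                s for s in served
                if s.server_id == pat.server_id
                and s.service_start < pat.arrival_time < s.service_end
            ]
            if not blocking:
                continue
            other_waiting = [
                q for q in served
                if q.ctype == "acute" and q.pid != pat.pid
                and q.server_id == pat.server_id
                and q.arrival_time <= pat.arrival_time
                and q.service_start >= pat.arrival_time
            ]
            if other_waiting:
                continue
            assert pat.service_start == blocking[0].service_end
            checked += 1
        assert checked >= 3

    def test_idle_gp_serves_acute_immediately(self):
        log = build_fhu(self._fhu_single_gp()).run(21, 4 * MINUTES_PER_WEEK)
        immediate = [p for p in log.served()
                     if p.ctype == "acute" and p.waiting_minutes == 0]
        assert immediate  # an acute patient finding a free GP starts at once


class TestSystemInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_per_stream(self, seed):
        prof = generate_unit_profile(seed, "PHCC", scale=0.15)
        log = build_model(prof).run(seed, 3 * MINUTES_PER_WEEK)
        for ctype, c in log.counts().items():
            assert c["arrivals"] == c["served"] + c["in_system"], ctype

    @pytest.mark.parametrize("model_type", ["PHCC", "FHU"])
    def test_no_server_overlap_and_timestamp_ordering(self, model_type):
        prof = generate_unit_profile(1, model_type, scale=0.3)
        log = build_model(prof).run(4, 3 * MINUTES_PER_WEEK)
        by_server: dict = {}
        for p in log.served():
            assert p.request_time <= p.arrival_time <= p.service_start <= p.service_end
            by_server.setdefault(p.server_id, []).append(p)
        assert by_server
        for services in by_server.values():
            services.sort(key=lambda p: p.service_start)
            for a, b in zip(services, services[1:]):
                assert a.service_end <= b.service_start

    def test_fhu_registered_routing(self, small_fhu):
        """Every non-acute medical visit in a FHU is served by the
        patient's own registered GP."""
        log = build_fhu(small_fhu).run(6, 3 * MINUTES_PER_WEEK)
        medical = [p for p in log.served() if p.ctype == "medical"]
        assert medical
        for p in medical:
            assert p.server_id == p.gp_id

    def test_seeded_runs_are_byte_identical(self, small_phcc):
        log_a = build_phcc(small_phcc).run(13, 2 * MINUTES_PER_WEEK)
        log_b = build_phcc(small_phcc).run(13, 2 * MINUTES_PER_WEEK)
        assert log_a.to_dataframe().to_csv(index=False) == log_b.to_dataframe().to_csv(index=False)

    def test_distinct_seeds_differ(self, small_phcc):
        log_a = build_phcc(small_phcc).run(13, 2 * MINUTES_PER_WEEK)
        log_b = build_phcc(small_phcc).run(14, 2 * MINUTES_PER_WEEK)
        assert log_a.to_dataframe().to_csv(index=False) != log_b.to_dataframe().to_csv(index=False)
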