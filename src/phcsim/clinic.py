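"""Executable clinic models: patient flow through a PHCC or FHU.

The two organizational models share one event-driven machinery and differ
in three configured behaviours:

* **PHCC** — only medical consultations are scheduled (appointment book);
  nursing type 1/2 are first-come-first-served walk-in queues on a nurse
  pool; acute cases are handled by a separate facility with its own
  timetable and exclusively allocated GPs; ~10% of demand comes from
  patients not registered with any GP (booked with the GP who has the
  earliest availability).
* **FHU** — medical *and* nursing consultations are scheduled; every
  patient is registered with a GP and booked with that GP; acute cases
  walk in during normal working hours and are seen with non-preemptive
  priority, by their own GP when on duty.

Completed consultations re-enter the system with a configurable
probability after a sampled delay (follow-up consultations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .kernel import (
    MINUTES_PER_DAY,
    DistributionSpec,
    EventCalendar,
    RandomStream,
    WeeklyTimetable,
    day_of,
    round_half_up,
)
from .profiles import FHU, PHCC, UnitProfile

__all__ = [
    "Patient",
    "AppointmentBook",
    "SimulationLog",
    "CapacityError",
    "ModelTypeError",
    "ClinicModel",
    "build_phcc",
    "build_fhu",
    "generate_arrivals",
    "book_appointment",
    "handle_reentry",
]

# Event priorities at equal times: service completions free servers before
# new arrivals are considered; openings precede arrivals.
_PRIO_END = 0
_PRIO_OPEN = 1
_PRIO_ARRIVAL = 2
_PRIO_BOOKING = 3


class CapacityError(RuntimeError):
    """A booking targeted a clinician with zero lifetime capacity."""


class ModelTypeError(ValueError):
    """Profile model_type does not match the requested builder."""


class Patient:
    """One consultation request travelling through the model."""

    __slots__ = (
        "pid",
        "ctype",
        "registered",
        "gp_id",
        "request_time",
        "booked_day",
        "arrival_time",
        "service_start",
        "service_end",
        "server_id",
        "pathway",
        "is_reentry",
    )

    def __init__(self, pid: int, ctype: str, registered: bool, gp_id: Optional[str],
                 request_time: int, pathway: str, is_reentry: bool = False):
        self.pid = pid
        self.ctype = ctype
        self.registered = registered
        self.gp_id = gp_id
        self.request_time = request_time
        self.booked_day: Optional[int] = None
        self.arrival_time: Optional[int] = None
        self.service_start: Optional[int] = None
        self.service_end: Optional[int] = None
        self.server_id: Optional[str] = None
        self.pathway = pathway  # "scheduled" | "walkin" | "acute"
        self.is_reentry = is_reentry

    @property
    def served(self) -> bool:
        return self.service_end is not None

    @property
    def waiting_minutes(self) -> Optional[int]:
        if self.service_start is None or self.arrival_time is None:
            return None
        return self.service_start - self.arrival_time

    @property
    def days_to_appointment(self) -> Optional[int]:
        if self.booked_day is None:
            return None
        return self.booked_day - day_of(self.request_time)


@dataclass
class SimulationLog:
    """Timestamped record of one run; the sole source of all indicators."""

    unit_id: str
    seed: int
    horizon: int
    warmup_boundary: Optional[int]
    patients: list[Patient] = field(default_factory=list)

    def served(self) -> list[Patient]:
        return [p for p in self.patients if p.served]

    def counts(self) -> dict[str, dict[str, int]]:
        """Per consultation type: arrivals generated, served, in-system."""
        out: dict[str, dict[str, int]] = {}
        for p in self.patients:
            c = out.setdefault(p.ctype, {"arrivals": 0, "served": 0, "in_system": 0})
            c["arrivals"] += 1
            c["served" if p.served else "in_system"] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "unit_id": self.unit_id,
                "pid": p.pid,
                "type": p.ctype,
                "registered": p.registered,
                "gp_id": p.gp_id,
                "pathway": p.pathway,
                "is_reentry": p.is_reentry,
                "request_time": p.request_time,
                "booked_day": p.booked_day,
                "arrival_time": p.arrival_time,
                "service_start": p.service_start,
                "service_end": p.service_end,
                "server_id": p.server_id,
                "served": p.served,
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class AppointmentBook:
    """Per-clinician, per-day slot ledger.

    Each clinician contributes ``window_minutes // slot_length`` slots per
    working day; bookings consume one or more contiguous slots and the
    ledger extends lazily into the future (the booking horizon is
    unbounded).
    """

    def __init__(self) -> None:
        self._slot_length: dict[str, int] = {}
        self._windows: dict[str, WeeklyTimetable] = {}
        self._booked: dict[tuple[str, int], int] = {}

    def register(self, cid: str, windows: WeeklyTimetable, slot_length: int) -> None:
        self._slot_length[cid] = slot_length
        self._windows[cid] = windows

    @property
    def clinicians(self) -> list[str]:
        return list(self._slot_length)

    def _day_window(self, cid: str, day: int) -> Optional[tuple[int, int]]:
        ivs = self._windows[cid].day_windows(day)
        return ivs[0] if ivs else None

    def capacity(self, cid: str, day: int) -> int:
        w = self._day_window(cid, day)
        if w is None:
            return 0
        return (w[1] - w[0]) // self._slot_length[cid]

    def booked(self, cid: str, day: int) -> int:
        return self._booked.get((cid, day), 0)

    def weekly_capacity(self, cid: str) -> int:
        return sum(self.capacity(cid, d) for d in range(7))

    def earliest_free_day(self, cid: str, request_day: int, slots_needed: int = 1) -> int:
        """First day strictly after ``request_day`` able to take the booking."""
        if self.weekly_capacity(cid) < slots_needed:
            raise CapacityError(f"clinician {cid!r} has no bookable capacity")
        day = request_day + 1
        while True:
            if self.capacity(cid, day) - self.booked(cid, day) >= slots_needed:
                return day
            day += 1

    def book(self, cid: str, day: int, slots_needed: int = 1) -> int:
        """Consume slots; returns the absolute arrival minute of the booking."""
        start_slot = self.booked(cid, day)
        if start_slot + slots_needed > self.capacity(cid, day):
            raise CapacityError(f"overbooking {cid!r} on day {day}")
        self._booked[(cid, day)] = start_slot + slots_needed
        window = self._day_window(cid, day)
        assert window is not None
        return day * MINUTES_PER_DAY + window[0] + start_slot * self._slot_length[cid]


def book_appointment(
    book: AppointmentBook,
    patient: Patient,
    request_day: int,
    candidates: list[str],
    slots_needed: int = 1,
) -> tuple[str, int, int]:
    """Book the earliest available day strictly after the request day.

    Registered patients pass their own clinician as sole candidate;
    unregistered patients (PHCC) pass every bookable GP and the one with
    the earliest availability wins (ties broken by candidate order).
    Returns ``(clinician_id, booked_day, arrival_minute)``.
    """
    if not candidates:
        raise CapacityError("no candidate clinicians to book with")
    best: Optional[tuple[int, int, str]] = None  # (day, order, cid)
    for order, cid in enumerate(candidates):
        day = book.earliest_free_day(cid, request_day, slots_needed)
        if best is None or day < best[0]:
            best = (day, order, cid)
    day, _, cid = best
    arrival = book.book(cid, day, slots_needed)
    patient.booked_day = day
    patient.arrival_time = arrival
    patient.server_id = None  # assigned when served
    return cid, day, arrival


def generate_arrivals(
    profile: UnitProfile, stream: RandomStream, horizon: int
) -> list[tuple[int, str, bool]]:
    """External consultation requests over ``[0, horizon)``.

    One Poisson stream per consultation type, generated directly on the
    stream's opening timetable (scheduled streams on working days, acute
    on the acute timetable), so request times land only inside open hours.
    ``daily_demand_rate`` is the expected total across types per working
    day; the weekly volume ``rate x working days`` is split by the type
    profile.  Registration status is Bernoulli(1 - unregistered_fraction).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    sched_tt = profile.scheduled_timetable
    weekly_total = profile.daily_demand_rate * sched_tt.open_days_per_week
    out: list[tuple[int, str, bool]] = []
    for ctype in ("medical", "acute", "nursing1", "nursing2"):
        share = profile.type_profile.get(ctype, 0.0)
        if share <= 0:
            continue
        # per-type substreams: one stream's demand never perturbs another's
        rng = stream.substream(f"arrivals-{ctype}").rng
        reg_rng = stream.substream(f"registration-{ctype}").rng
        tt = profile.effective_acute_timetable if ctype == "acute" else sched_tt
        if tt.weekly_open_minutes == 0:
            continue
        rate_per_min = weekly_total * share / tt.weekly_open_minutes
        if rate_per_min <= 0:
            continue
        intervals = list(tt.iter_open_intervals(0, horizon))
        lengths = [b - a for a, b in intervals]
        cum = [0]
        for ln in lengths:
            cum.append(cum[-1] + ln)
        total_open = cum[-1]
        mean_gap = 1.0 / rate_per_min
        t_open = 0.0
        idx = 0
        # exponential gaps in collapsed open-time, mapped back to absolute time
        while True:
            t_open += rng.exponential(mean_gap)
            if t_open >= total_open:
                break
            while cum[idx + 1] <= t_open:
                idx += 1
            t_abs = intervals[idx][0] + int(t_open - cum[idx])
            registered = bool(reg_rng.random() >= profile.unregistered_fraction)
            out.append((t_abs, ctype, registered))
    out.sort(key=lambda x: (x[0], x[1]))
    return out


def handle_reentry(
    record: Patient, profile: UnitProfile, stream: RandomStream
) -> Optional[tuple[int, str, bool]]:
    """Follow-up re-entry after a completed consultation.

    With probability ``reentry_prob`` the patient generates a new request
    of the same type at ``service_end + delay`` (delay sampled in days);
    otherwise the patient exits the system.
    """
    if record.service_end is None:
        raise ValueError("re-entry requires a completed consultation")
    rng = stream.rng
    if rng.random() >= profile.reentry_prob:
        return None
    delay_days = float(profile.reentry_delay_days.sample(rng))
    t_new = record.service_end + round_half_up(delay_days * MINUTES_PER_DAY)
    return (t_new, record.ctype, record.registered)


class _Server:
    __slots__ = ("cid", "role", "windows", "slot_length", "busy", "present", "acute_q", "station")

    def __init__(self, cid: str, role: str, windows: WeeklyTimetable, slot_length: int):
        self.cid = cid
        self.role = role
        self.windows = windows
        self.slot_length = slot_length
        self.busy = False
        self.present: list[Patient] = []  # FIFO of booked patients in the waiting room
        self.acute_q: list[Patient] = []  # FHU acute walk-ins (non-preemptive priority)
        self.station: Optional[str] = None


def _staggered_windows(
    base: WeeklyTimetable,
    index: int,
    group_size: int,
    daily_minutes: dict[int, int],
    *,
    wrap: bool = False,
) -> WeeklyTimetable:
    """Anchor a clinician's daily clinical minutes inside the unit opening
    hours, staggering start offsets across the group so the unit keeps
    coverage over its whole open day.

    With ``wrap=False`` the shift is contiguous and offsets spread over
    ``[0, span - shift]`` (used for booked streams, whose agendas must be
    one block).  With ``wrap=True`` shifts tile the open day modulo its
    length, giving near-constant pool coverage at every open minute (used
    for walk-in pools, where an uncovered late hour would otherwise carry
    its whole queue overnight)."""
    days: list[list[tuple[int, int]]] = []
    for d in range(7):
        ivs = base.days[d]
        m = daily_minutes.get(d, 0)
        if not ivs or m <= 0:
            days.append([])
            continue
        a, b = ivs[0]
        span = b - a
        m = min(m, span)
        if wrap and group_size > 1 and m < span:
            off = (index * span) // group_size
            end = off + m
            if end <= span:
                days.append([(a + off, a + end)])
            else:
                days.append([(a, a + end - span), (a + off, b)])
        else:
            off = (index * (span - m)) // max(1, group_size - 1) if group_size > 1 else 0
            days.append([(a + off, a + off + m)])
    return WeeklyTimetable(days)


class ClinicModel:
    """An executable unit model; ``run`` produces a :class:`SimulationLog`."""

    def __init__(self, profile: UnitProfile, *, scheduled_nursing: bool, acute_mode: str):
        self.profile = profile
        self.scheduled_nursing = scheduled_nursing
        self.acute_mode = acute_mode  # "facility" (PHCC) | "own_gp" (FHU)
        self._medical_slots = self._slots_needed("medical")
        self._n1_slots = self._slots_needed("nursing1")
        self._n2_slots = self._slots_needed("nursing2")

    # -- static structure ---------------------------------------------
    def _slots_needed(self, ctype: str) -> int:
        p = self.profile
        if ctype == "medical":
            mean = (
                p.medical_adult_fraction * p.duration_specs["medical_adult"].mean
                + (1 - p.medical_adult_fraction) * p.duration_specs["medical_other"].mean
            )
            slot = p.gps[0].slot_length if p.gps else 20
        else:
            mean = p.duration_specs[ctype].mean
            slot = p.nurses[0].slot_length if p.nurses else 20
        return max(1, math.ceil(mean / slot - 1e-9))

    def _build_servers(self) -> tuple[dict[str, _Server], AppointmentBook, dict[str, list[_Server]]]:
        p = self.profile
        servers: dict[str, _Server] = {}
        book = AppointmentBook()
        stations: dict[str, list[_Server]] = {}
        sched_tt = p.scheduled_timetable
        n_open = max(1, sched_tt.open_days_per_week)
        open_days = [d for d in range(7) if sched_tt.days[d]]

        bookable = p.bookable_gps
        for i, roster in enumerate(bookable):
            per_day = roster.weekly_clinical_minutes // n_open
            win = _staggered_windows(
                sched_tt, i, len(bookable), {d: per_day for d in open_days}
            )
            srv = _Server(roster.clinician_id, "gp", win, roster.slot_length)
            servers[srv.cid] = srv
            book.register(srv.cid, win, roster.slot_length)

        if self.acute_mode == "facility":
            acute_tt = p.effective_acute_timetable
            total_open = max(1, acute_tt.weekly_open_minutes)
            acute_group = p.acute_gps
            pool: list[_Server] = []
            for i, roster in enumerate(acute_group):
                weekly = roster.weekly_clinical_minutes
                daily = {
                    d: round(weekly * acute_tt.open_minutes(d) / total_open)
                    for d in range(7)
                    if acute_tt.days[d]
                }
                win = _staggered_windows(acute_tt, i, len(acute_group), daily, wrap=True)
                srv = _Server(roster.clinician_id, "gp", win, roster.slot_length)
                srv.station = "acute"
                servers[srv.cid] = srv
                pool.append(srv)
            stations["acute"] = pool

        nurse_pool: list[_Server] = []
        for i, roster in enumerate(p.nurses):
            per_day = roster.weekly_clinical_minutes // n_open
            win = _staggered_windows(
                sched_tt, i, len(p.nurses), {d: per_day for d in open_days},
                wrap=not self.scheduled_nursing,
            )
            srv = _Server(roster.clinician_id, "nurse", win, roster.slot_length)
            servers[srv.cid] = srv
            if self.scheduled_nursing:
                book.register(srv.cid, win, roster.slot_length)
            else:
                srv.station = "nursing"
                nurse_pool.append(srv)
        if not self.scheduled_nursing:
            stations["nursing"] = nurse_pool
        return servers, book, stations

    # -- execution ----------------------------------------------------
    def run(self, seed: int, horizon: int) -> SimulationLog:
        p = self.profile
        servers, book, stations = self._build_servers()
        cal = EventCalendar()
        log = SimulationLog(unit_id=p.unit_id, seed=seed, horizon=horizon, warmup_boundary=None)
        root = RandomStream(seed, f"run/{p.unit_id}")
        ctypes = ("medical", "acute", "nursing1", "nursing2")
        dur_rngs = {c: root.substream(f"durations-{c}").rng for c in ctypes}
        mix_rng = root.substream("medical-mix").rng
        gp_rngs = {c: root.substream(f"gp-assign-{c}").rng for c in ctypes}
        reentry_streams = {c: root.substream(f"reentry-{c}") for c in ctypes}

        bookable_ids = [r.clinician_id for r in p.bookable_gps]
        nurse_ids = [r.clinician_id for r in p.nurses]
        sched_tt = p.scheduled_timetable
        acute_tt = p.effective_acute_timetable
        pid_counter = 0

        def new_patient(ctype: str, registered: bool, request_time: int,
                        pathway: str, is_reentry: bool = False,
                        gp_id: Optional[str] = None) -> Patient:
            nonlocal pid_counter
            pid_counter += 1
            if gp_id is None and registered and bookable_ids:
                gp_id = bookable_ids[int(gp_rngs[ctype].integers(len(bookable_ids)))]
            pat = Patient(pid_counter, ctype, registered, gp_id, request_time,
                          pathway, is_reentry)
            log.patients.append(pat)
            return pat

        def pathway_of(ctype: str) -> str:
            if ctype == "medical":
                return "scheduled"
            if ctype == "acute":
                return "acute"
            return "scheduled" if self.scheduled_nursing else "walkin"

        def enqueue_request(pat: Patient) -> None:
            if pat.ctype == "medical" or (pat.ctype.startswith("nursing") and self.scheduled_nursing):
                cal.schedule(pat.request_time, _PRIO_BOOKING, "booking_request", pat)
            else:
                # walk-in: the request IS the arrival (shifted to opening hours)
                tt = acute_tt if pat.ctype == "acute" else sched_tt
                arr = pat.request_time if tt.is_open(pat.request_time) else tt.next_open(pat.request_time)
                pat.arrival_time = arr
                cal.schedule(arr, _PRIO_ARRIVAL, "arrival", pat)

        # external demand
        for t_req, ctype, registered in generate_arrivals(p, root, horizon):
            if self.acute_mode == "own_gp" or p.model_type == FHU:
                registered = True
            pat = new_patient(ctype, registered, t_req, pathway_of(ctype))
            enqueue_request(pat)

        # clinic/server opening events wake idle servers holding overnight queues
        n_days = horizon // MINUTES_PER_DAY + 2
        for srv in servers.values():
            for day in range(n_days):
                ivs = srv.windows.day_windows(day)
                if ivs:
                    t_open = day * MINUTES_PER_DAY + ivs[0][0]
                    if t_open <= horizon:
                        cal.schedule(t_open, _PRIO_OPEN, "clinic_open", srv)

        # -- service machinery ----------------------------------------
        def sample_minutes(ctype: str) -> int:
            if ctype == "medical":
                spec = (
                    p.duration_specs["medical_adult"]
                    if mix_rng.random() < p.medical_adult_fraction
                    else p.duration_specs["medical_other"]
                )
            else:
                spec = p.duration_specs[ctype]
            return max(1, round_half_up(float(spec.sample(dur_rngs[ctype]))))

        def start_service(srv: _Server, pat: Patient, now: int) -> None:
            dur = sample_minutes(pat.ctype)
            pat.service_start = now
            pat.service_end = now + dur
            pat.server_id = srv.cid
            srv.busy = True
            cal.schedule(now + dur, _PRIO_END, "service_end", (srv, pat))

        def try_start(srv: _Server, now: int) -> None:
            if srv.busy or not srv.windows.is_open(now):
                return
            if srv.acute_q:
                start_service(srv, srv.acute_q.pop(0), now)
            elif srv.present:
                start_service(srv, srv.present.pop(0), now)

        def try_start_station(name: str, now: int) -> None:
            pool = stations[name]
            queue = station_queues[name]
            for srv in pool:
                if not queue:
                    return
                if not srv.busy and srv.windows.is_open(now):
                    start_service(srv, queue.pop(0), now)

        station_queues: dict[str, list[Patient]] = {name: [] for name in stations}

        def choose_acute_server(pat: Patient, now: int) -> _Server:
            own = servers.get(pat.gp_id) if pat.gp_id else None
            if own is not None and own.windows.is_open(now):
                return own
            on_duty = [servers[c] for c in bookable_ids if servers[c].windows.is_open(now)]
            if on_duty:
                return min(on_duty, key=lambda s: (s.busy + len(s.acute_q), bookable_ids.index(s.cid)))
            candidates = [servers[c] for c in bookable_ids] or ([own] if own else [])
            if not candidates:
                raise CapacityError("no GP available for acute care")
            return min(candidates, key=lambda s: (s.windows.next_open(now), bookable_ids.index(s.cid) if s.cid in bookable_ids else 0))

        def dispatch_arrival(pat: Patient, now: int) -> None:
            if pat.pathway == "walkin":
                station_queues["nursing"].append(pat)
                try_start_station("nursing", now)
            elif pat.ctype == "acute" and self.acute_mode == "facility":
                station_queues["acute"].append(pat)
                try_start_station("acute", now)
            elif pat.ctype == "acute":  # own-GP priority walk-in
                srv = choose_acute_server(pat, now)
                srv.acute_q.append(pat)
                try_start(srv, now)
            else:
                srv = servers[pat.server_id] if pat.server_id else None
                assert srv is not None
                srv.present.append(pat)
                try_start(srv, now)

        def dispatch_booking(pat: Patient, now: int) -> None:
            if pat.ctype == "medical":
                candidates = [pat.gp_id] if (pat.registered and pat.gp_id) else list(bookable_ids)
                slots = self._medical_slots
            else:
                candidates = list(nurse_ids)
                slots = self._n1_slots if pat.ctype == "nursing1" else self._n2_slots
            cid, _day, arrival = book_appointment(book, pat, day_of(now), candidates, slots)
            pat.server_id = cid
            cal.schedule(arrival, _PRIO_ARRIVAL, "arrival", pat)

        def dispatch_end(srv: _Server, pat: Patient, now: int) -> None:
            srv.busy = False
            follow = handle_reentry(pat, p, reentry_streams[pat.ctype])
            if follow is not None:
                t_new, ctype, registered = follow
                if t_new <= horizon:
                    nxt = new_patient(ctype, registered, t_new, pathway_of(ctype),
                                      is_reentry=True, gp_id=pat.gp_id)
                    enqueue_request(nxt)
            if srv.station is not None:
                try_start_station(srv.station, now)
            else:
                try_start(srv, now)

        # -- event loop ------------------------------------------------
        while len(cal):
            t = cal.peek_time()
            if t is None or t > horizon:
                break
            ev = cal.pop()
            if ev.kind == "service_end":
                srv, pat = ev.payload
                dispatch_end(srv, pat, ev.time)
            elif ev.kind == "clinic_open":
                srv = ev.payload
                if srv.station is not None:
                    try_start_station(srv.station, ev.time)
                else:
                    try_start(srv, ev.time)
            elif ev.kind == "arrival":
                dispatch_arrival(ev.payload, ev.time)
            elif ev.kind == "booking_request":
                dispatch_booking(ev.payload, ev.time)
        return log


def build_phcc(profile: UnitProfile) -> ClinicModel:
    """Executable PHCC model: scheduled medical stream, walk-in nursing
    queues, separate acute facility with dedicated GPs, unregistered
    patients booked with the earliest-available GP."""
    if profile.model_type != PHCC:
        raise ModelTypeError(f"expected a PHCC profile, got {profile.model_type}")
    return ClinicModel(profile, scheduled_nursing=False, acute_mode="facility")


def build_fhu(profile: UnitProfile) -> ClinicModel:
    """Executable FHU model: scheduled medical and nursing streams; acute
    patients as non-preemptive priority walk-ins in their own GP's day."""
    if profile.model_type != FHU:
        raise ModelTypeError(f"expected a FHU profile, got {profile.model_type}")
    if profile.unregistered_fraction != 0.0:
        raise ModelTypeError("FHU requires all patients registered with a GP")
    return ClinicModel(profile, scheduled_nursing=True, acute_mode="own_gp")


def build_model(profile: UnitProfile) -> ClinicModel:
    return build_phcc(profile) if profile.model_type == PHCC else build_fhu(profile)
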