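# Methods

## Scope and model

`phcsim` is a stochastic discrete-event simulation of a single Portuguese
primary-care unit under two organizational models:

* **PHCC** (primary health care centre): opens 8:00–20:00 on working days
  with a separate acute facility also open 10:00–20:00 at weekends; only
  medical consultations are scheduled; nursing type 1 (diabetes, child,
  maternal) and type 2 (vaccination, other treatments) are
  first-come-first-served walk-in queues on a nurse pool; acute cases are
  seen in the acute facility by GPs allocated exclusively to it; a
  fraction of demand (default 10%) comes from patients not registered
  with any GP; GPs hold 42 h/week contracts of which 6 h are
  administrative.
* **FHU** (family health unit): opens 8:00–20:00 on working days only;
  medical *and* nursing consultations are scheduled; every patient is
  registered with a GP and is booked with that GP; acute cases walk in
  during normal hours and are seen with non-preemptive priority —
  preferentially by their own GP; GPs hold 35 h/week fully clinical
  contracts; cost constants switch to the mixed-remuneration values.

Four consultation types flow through five stages: external request,
booking (scheduled streams), arrival, service, and probabilistic
follow-up re-entry.

## Event kernel

Time is integer minutes from 00:00 on the Monday opening the first
simulated week. The calendar is a binary heap keyed by
`(time, priority, insertion sequence)`: completions free servers before
same-minute arrivals are dispatched, and ties are FIFO. Scheduling an
event before the last popped time raises a causality error. All
randomness flows through named substreams keyed by `(seed, label)`, one
per consultation type and purpose (arrivals, registration, durations, GP
assignment, re-entry), so two runs with the same profile and seed are
byte-identical and deleting one demand stream leaves the trajectories of
the others unchanged.

Durations are sampled in natural-scale minutes and rounded half-up to
whole minutes (minimum 1) for reproducible logs. The lognormal family is
parameterized by its natural-scale mean m and standard deviation s, with
underlying normal parameters `mu = ln(m^2/sqrt(m^2+s^2))`,
`sigma^2 = ln(1+s^2/m^2)`. "Average"-type inputs are read as exponential
for inter-arrival times and as fixed values for nursing durations; both
readings are per-field configurable through `DistributionSpec`.

## Demand

`daily_demand_rate` is the expected number of *external* requests per
working day; the weekly volume (rate x working days) is split across
types by the type-profile probabilities, and each type's stream is a
Poisson process over its own opening timetable (scheduled and nursing
streams on working days; acute on the acute timetable). Generating
per-type streams directly on open hours is distributionally equivalent to
generating on the full timetable and shifting closed-period arrivals to
the next opening, without Monday-morning pile-up artifacts. Completed
consultations re-enter with probability `reentry_prob` (default 0.25)
after a sampled delay (default fixed 30 days), multiplying effective
demand by 1/(1-p) in steady state.

## Booking and service discipline

Each bookable clinician contributes `clinical minutes / slot length`
slots per working day (GP slots 20 min; nurse slots 10 min, a type-1
nursing booking consuming two). A request books the earliest day
*strictly after* the request day with free capacity — own GP for
registered patients, earliest-available clinician for unregistered PHCC
patients and FHU nursing — and the patient arrives exactly at the slot
start (no no-shows). Days-to-appointment is the calendar-day difference;
the book extends lazily, so waits may grow without bound under overload.

Clinicians' clinical minutes are spread evenly over working days and
anchored inside the unit opening hours. Booked agendas are contiguous
blocks with staggered starts across the group; walk-in pools (PHCC
nursing, acute facility) instead tile shifts around the open day modulo
its length, keeping pool coverage near-constant — with contiguous
staggering an uncovered late hour would carry its whole queue overnight.
A consultation in progress at closing finishes; no new service starts
after close; walk-in patients still queued at close are carried to the
next opening rather than dropped, which keeps the conservation identity
(arrivals = served + in-system) exact. FHU acute walk-ins go to their own
GP when on duty; because a 420-minute clinical day cannot cover a
12-hour opening, an acute arrival outside its own GP's shift falls back
deterministically to an on-duty colleague (shortest queue, then roster
order) — own-GP routing is strict only for scheduled medical visits.

## Conversion procedure

A PHCC is split into FHU subunits by: (1) returning acute-dedicated GPs
to the booked pool, then partitioning GPs into the fewest groups of 6–9
with sizes differing by at most one, larger groups first (20 GPs →
7/7/6); nurses are partitioned likewise, paired in order, and clipped
into 6–9 with an audit note if the source ratio is incompatible; each
subunit gets 5 administrative staff; (2) removing the acute timetable;
(3) scheduling nursing; (4) switching rosters (35 h, no administrative
time) and cost constants to FHU values; (5) splitting demand in
proportion to GP share, with former unregistered demand folded into the
fully registered split. Sources with fewer than six GPs yield one
flagged undersized unit; 10 and 11 GPs admit no 6–9 partition and yield
one flagged oversized unit. Converting a FHU again is rejected.

## Indicators, costs, output analysis

Indicators use only visits completed inside the collection window:
waiting-room time (`service_start - arrival`) per stream, mean
days-to-appointment (scheduled medical), and annual per-capita volumes
(window count x 52/collection-weeks, divided by clinical GP head-count
for medical, all GPs for acute, nurses for nursing; the 52/50
annualization is configurable). Costs apply per-consultation constants
uniformly to all completed consultations: professionals €13.25 /
diagnostics-drugs €39.20 per consultation for PHCCs, €16.32 / €29.20 for
FHUs, each scaled by an `uplift` factor (default 1.0) for sensitivity
runs. Percentage differences of averages are rounded half away from zero
to integers, with raw values reported alongside.

A trial runs n independently seeded replications (default 5, seeds
`base_seed + r`) of warm-up (default 52 weeks, discarded) plus collection
(default 50 weeks); per-indicator intervals are Student-t on run means.
Validation is closed-interval enclosure of an observed value. Scenario
comparison reports both intervals and the rounded percentage difference
of means per indicator.

## Synthetic units

Profile defaults emulate the national full-scale averages: 20 GPs (3
staffing the acute facility), 20 nurses, ~1,519 registered patients per
GP (~30,400 per unit, implying ~3,376 unregistered at a 10% unregistered
demand share), and external demand calibrated so a full-scale PHCC
performs ≈75,000 medical consultations per collection year once re-entry
is included (the suite checks a ±15% sanity band; a seeded ±10% jitter
on demand and list size makes panels heterogeneous without moving the
mean). The type profile (medical 0.65, acute 1/6, nursing 0.10/0.083),
consultation durations (medical lognormal 15±5 min, acute lognormal
12±5, nursing fixed 20/10), nurses' consultation hours (14 h/week, the
rest standing for unmodelled duties), and re-entry behaviour are
illustrative defaults, stated in the profile and trivially overridden.
The default panel shape is 13 PHCCs + 6 FHUs.

What the generator does *not* emulate: real units' demand seasonality and
within-day arrival profiles, no-shows, heterogeneous list sizes per GP,
and — most importantly — the near-saturated booking regime behind
multi-week appointment backlogs. Synthetic defaults put medical slot
utilization near 0.8, so absolute days-to-appointment sit near the
next-free-day floor (~1.5 days) rather than at tens of days, and
waiting-room levels are likewise compressed. Passing tests therefore
demonstrate correct mechanics and the *direction* of conversion effects
(booking delay falls, nursing waits fall under scheduling, professional
costs per consultation rise while diagnostics costs fall), not the
published magnitudes, which depend on nineteen unpublished unit-level
activity reports.

## Numerical and design choices

* Integer-minute clock; durations rounded half-up, minimum 1 minute.
* Event ties: service_end < clinic_open < arrival < booking_request,
  then FIFO.
* Booking ties across candidate clinicians break by candidate order;
  walk-in pools assign the lowest-indexed idle on-duty server.
* Empty collection windows yield zero counts and absent (None) means
  rather than zeros.
* Intervals with zero variance degenerate to a point; fewer than two
  replications raise rather than return a pseudo-interval.
* Problem sizes in the test and acceptance workloads (quarter-scale
  conversion fixture at the full 5x(52+50)-week protocol, 500 coverage
  trials at 1+1 weeks, 10x35-day queueing-oracle runs) were chosen as
  the smallest sizes at which the statistical checks have comfortable
  power.

## Known limitations

Single-unit models only (no inter-unit patient movement or shared
demand); no no-show or abandonment behaviour; capitation ceilings and
the other mixed-remuneration components are not modelled beyond the
per-consultation constants; acute coverage at very small scales (a
single acute GP cannot cover a 12-hour opening) produces long carried
waits that real rota design would avoid.
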