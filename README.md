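# phcsim

Stochastic discrete-event simulation of Portuguese primary-care units,
for health-services operational research: it compares the traditional
**primary health care centre** (PHCC) organizational model with the
reformed **family health unit** (FHU) model on accessibility,
productivity and cost indicators, and simulates the conversion of a PHCC
into FHU subunits.

A unit model tracks four consultation streams — medical, emergency/acute,
and nursing types 1 and 2 — through request, appointment booking (or
walk-in queueing), service and probabilistic follow-up re-entry. PHCCs
schedule only medical care, run walk-in nursing queues and a separate
acute facility with dedicated GPs, and serve ~10% unregistered demand;
FHUs schedule medical *and* nursing care, register every patient with a
GP, and absorb acute cases as non-preemptive priority walk-ins during
normal hours. The output-analysis protocol follows standard simulation
practice: trials of 5 independently seeded runs, a 52-week warm-up, a
50-week collection year, Student-t 95% confidence intervals on run
means (`mean ± t_{0.975,n-1} · s/√n`), validation by interval enclosure
of observed values, and comparison via rounded percentage differences of
averages, `round(100·(after−before)/before)`. Costs use per-consultation
constants (PHCC €13.25 professionals / €39.20 diagnostics-drugs; FHU
€16.32 / €29.20) with an optional sensitivity uplift.

See `docs/methods.md` for the full model description and its
assumptions.

## Worked example

```python
from phcsim import (TrialSpec, compare_scenarios, generate_unit_profile,
                    run_trial, split_unit)

phcc = generate_unit_profile(seed=0, model_type="PHCC", scale=0.25)
plan = split_unit(phcc)                      # PHCC -> FHU subunit(s)
spec = TrialSpec(n_runs=5, warmup_weeks=52, collection_weeks=50, base_seed=7)
before = run_trial(phcc, spec)
after = run_trial(plan.fhus[0], spec)
table = compare_scenarios(before, after)
for name in ("days_to_appointment", "waiting_room_nursing1", "cost_total"):
    row = next(r for r in table.rows if r["indicator"] == name)
    print(f"{name:25s} {row['before_mean']:12.2f} -> {row['after_mean']:12.2f}"
          f"  ({row['pct_diff']:+d}%)")
```

prints

```
days_to_appointment               1.54 ->         1.45  (-5%)
waiting_room_nursing1            17.00 ->         0.00  (-100%)
cost_total                  1384330.05 ->   1204028.03  (-13%)
```

Converting this quarter-scale synthetic centre shortens the mean wait
for a medical appointment (bookings land on the next free day sooner
because the former acute-facility GPs rejoin booked care), eliminates
nursing waiting-room time entirely (scheduled slots replace walk-in
queues), and lowers total cost under the FHU per-consultation constants;
the mean-wait drop from 17.0 to 0.0 minutes shows why the percentage
difference of averages reports −100% for the nursing stream.

The same pipeline is available from the shell:

```bash
phcsim generate-fixtures --seed 0 --scale 0.25 --out-dir fixtures
phcsim convert fixtures/synthetic-phcc-01.yaml --out-dir converted
phcsim simulate fixtures/synthetic-phcc-01.yaml --seed 7 --runs 5 --out-dir results
phcsim compare fixtures/synthetic-phcc-01.yaml converted/*.yaml --out comparison.csv
```

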