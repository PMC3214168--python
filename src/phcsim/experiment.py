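"""Output-analysis protocol: replicated trials, warm-up, confidence
intervals, validation by interval enclosure, and scenario comparison.

A *trial* is a set of independently seeded replications (*runs*) of one
unit model.  Each run simulates a warm-up period (discarded) followed by a
collection period; per-run indicator values across runs yield Student-t
confidence intervals.  A model is accepted ("validated") when its interval
encloses the observed real-world value.  Scenario comparison reports, per
indicator, both intervals and the rounded percentage difference of the
means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kernel import MINUTES_PER_WEEK
from .profiles import UnitProfile
from .clinic import build_model
from .indicators import INDICATOR_NAMES, PIReport, compute_pis, percent_diff_of_averages, percent_diff_raw

__all__ = [
    "TrialSpec",
    "IntervalEstimate",
    "TrialResult",
    "ComparisonTable",
    "run_trial",
    "confidence_interval",
    "validate_against_observed",
    "compare_scenarios",
    "InsufficientReplicationsError",
]


class InsufficientReplicationsError(ValueError):
    """Fewer than two replications: no interval can be formed."""


@dataclass(frozen=True)
class TrialSpec:
    """Protocol parameters for one trial of replicated runs."""

    n_runs: int = 5
    warmup_weeks: int = 52
    collection_weeks: int = 50
    base_seed: int = 0
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise InsufficientReplicationsError("a trial needs at least 2 runs")
        if self.warmup_weeks < 1 or self.collection_weeks < 1:
            raise ValueError("warm-up and collection periods must be >= 1 week")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")

    @property
    def horizon(self) -> int:
        return (self.warmup_weeks + self.collection_weeks) * MINUTES_PER_WEEK

    @property
    def collection_start(self) -> int:
        return self.warmup_weeks * MINUTES_PER_WEEK


@dataclass(frozen=True)
class IntervalEstimate:
    mean: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("interval must contain its mean")


@dataclass
class TrialResult:
    profile: UnitProfile
    spec: TrialSpec
    reports: list[PIReport]
    intervals: dict[str, Optional[IntervalEstimate]]
    seeds: list[int]

    def mean(self, indicator: str) -> Optional[float]:
        iv = self.intervals.get(indicator)
        return iv.mean if iv is not None else None

    def per_run_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.reports])
        df.insert(0, "seed", self.seeds)
        df.insert(0, "unit_id", self.profile.unit_id)
        return df

    def intervals_frame(self) -> pd.DataFrame:
        rows = []
        for name in INDICATOR_NAMES:
            iv = self.intervals.get(name)
            rows.append(
                {
                    "unit_id": self.profile.unit_id,
                    "indicator": name,
                    "mean": iv.mean if iv else None,
                    "lower": iv.lower if iv else None,
                    "upper": iv.upper if iv else None,
                    "level": iv.level if iv else None,
                }
            )
        return pd.DataFrame(rows)


def confidence_interval(values: Sequence[float], level: float = 0.95) -> IntervalEstimate:
    """Student-t interval on run means: mean +/- t_{(1+level)/2, n-1} * sd/sqrt(n)."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise InsufficientReplicationsError("need >= 2 replications for an interval")
    n = len(vals)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    half = stats.t.ppf((1 + level) / 2, n - 1) * sd / math.sqrt(n)
    return IntervalEstimate(mean=mean, lower=mean - half, upper=mean + half, level=level)


def validate_against_observed(interval: IntervalEstimate, observed: float) -> bool:
    """Closed-interval enclosure: the model is accepted iff
    lower <= observed <= upper."""
    return interval.lower <= observed <= interval.upper


def run_trial(profile: UnitProfile, spec: TrialSpec = TrialSpec()) -> TrialResult:
    """Run ``n_runs`` independently seeded replications and form intervals.

    Run ``r`` uses seed ``base_seed + r``; indicators are computed on the
    collection window only.  Indicators absent in some run (no qualifying
    visits) yield no interval.
    """
    model = build_model(profile)
    reports: list[PIReport] = []
    seeds: list[int] = []
    for r in range(spec.n_runs):
        seed = spec.base_seed + r
        seeds.append(seed)
        try:
            log = model.run(seed, spec.horizon)
            log.warmup_boundary = spec.collection_start
            reports.append(
                compute_pis(log, spec.collection_start, spec.horizon, profile)
            )
        except Exception as exc:
            raise RuntimeError(f"run {r} (seed {seed}) failed") from exc
    intervals: dict[str, Optional[IntervalEstimate]] = {}
    for name in INDICATOR_NAMES:
        vals = [getattr(rep, name) for rep in reports]
        if any(v is None for v in vals):
            intervals[name] = None
        else:
            intervals[name] = confidence_interval(vals, spec.confidence_level)
    return TrialResult(profile=profile, spec=spec, reports=reports,
                       intervals=intervals, seeds=seeds)


@dataclass
class ComparisonTable:
    """Before/after (or PHCC/FHU) indicator comparison.

    Per indicator: both interval estimates and the percentage difference
    of the two run-averaged means, rounded half away from zero (raw
    percentages are kept alongside)."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def diff(self, indicator: str) -> Optional[int]:
        for row in self.rows:
            if row["indicator"] == indicator:
                return row["pct_diff"]
        raise KeyError(indicator)


def compare_scenarios(before: TrialResult, after: TrialResult) -> ComparisonTable:
    """Row per indicator with both intervals and the rounded percentage
    difference of averages; raises on indicator-set mismatch."""
    if set(before.intervals) != set(after.intervals):
        raise ValueError("scenario results carry different indicator sets")
    table = ComparisonTable()
    for name in INDICATOR_NAMES:
        b, a = before.intervals.get(name), after.intervals.get(name)
        row: dict = {"indicator": name}
        for tag, iv in (("before", b), ("after", a)):
            row[f"{tag}_mean"] = iv.mean if iv else None
            row[f"{tag}_lower"] = iv.lower if iv else None
            row[f"{tag}_upper"] = iv.upper if iv else None
        if b is not None and a is not None and b.mean != 0:
            row["pct_diff"] = percent_diff_of_averages(b.mean, a.mean)
            row["pct_diff_raw"] = percent_diff_raw(b.mean, a.mean)
        else:
            row["pct_diff"] = None
            row["pct_diff_raw"] = None
        table.rows.append(row)
    return table


def validation_report(
    result: TrialResult, observed: dict[str, float]
) -> pd.DataFrame:
    """Real vs model intervals with relative variation of each CI endpoint
    against the observed value (percent)."""
    rows = []
    for name, obs in observed.items():
        iv = result.intervals.get(name)
        if iv is None:
            rows.append({"indicator": name, "real": obs, "enclosed": False})
            continue
        rows.append(
            {
                "indicator": name,
                "real": obs,
                "model_lower": iv.lower,
                "model_upper": iv.upper,
                "variation_lower_pct": 100.0 * (iv.lower - obs) / obs if obs else None,
                "variation_upper_pct": 100.0 * (iv.upper - obs) / obs if obs else None,
                "enclosed": validate_against_observed(iv, obs),
            }
        )
    return pd.DataFrame(rows)
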