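"""Performance indicators and the per-consultation cost model.

All indicators are pure functions of the :class:`~phcsim.clinic.SimulationLog`
restricted to the collection window: accessibility (days to appointment,
waiting-room minutes per stream), productivity (annual consultations per
clinician) and costs (per-consultation euro constants, with an optional
sensitivity uplift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .kernel import MINUTES_PER_WEEK
from .profiles import CostParameters, UnitProfile
from .clinic import SimulationLog

__all__ = [
    "PIReport",
    "CostBreakdown",
    "compute_pis",
    "compute_costs",
    "percent_diff_of_averages",
    "percent_diff_raw",
    "INDICATOR_NAMES",
]

INDICATOR_NAMES = (
    "days_to_appointment",
    "waiting_room_medical",
    "waiting_room_acute",
    "waiting_room_nursing1",
    "waiting_room_nursing2",
    "annual_consultations_per_gp",
    "annual_acute_per_gp",
    "annual_nursing_per_nurse",
    "cost_professionals",
    "cost_diagnostics",
    "cost_total",
)


@dataclass(frozen=True)
class CostBreakdown:
    professionals: float
    diagnostics: float

    @property
    def total(self) -> float:
        return self.professionals + self.diagnostics


@dataclass
class PIReport:
    """One run's indicator values.

    Mean-based indicators are ``None`` when no qualifying visit completed
    inside the collection window (flagged absent rather than zero).
    """

    days_to_appointment: Optional[float]
    waiting_room_medical: Optional[float]
    waiting_room_acute: Optional[float]
    waiting_room_nursing1: Optional[float]
    waiting_room_nursing2: Optional[float]
    annual_consultations_per_gp: float
    annual_acute_per_gp: float
    annual_nursing_per_nurse: float
    cost_professionals: float
    cost_diagnostics: float
    cost_total: float
    counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in INDICATOR_NAMES}


def _mean(values: list[float]) -> Optional[float]:
    return sum(values) / len(values) if values else None


def compute_pis(
    log: SimulationLog,
    collection_start: int,
    collection_end: int,
    profile: UnitProfile,
    *,
    annualize: bool = True,
) -> PIReport:
    """All indicators from visits *completed* inside ``[start, end)``.

    Waiting-room time is ``service_start - arrival_time``; days to
    appointment is ``booked_day - request_day`` over scheduled medical
    visits.  Per-capita annual rates scale the window count by
    ``52 / collection_weeks`` (if ``annualize``) and divide by the
    relevant head-count — clinical (non-acute-dedicated) GPs for medical,
    all GPs for acute, nurses for nursing.
    """
    if collection_end <= collection_start:
        raise ValueError("collection window must have positive length")
    weeks = (collection_end - collection_start) / MINUTES_PER_WEEK
    factor = (52.0 / weeks) if annualize else 1.0

    visits = [
        p
        for p in log.patients
        if p.served and collection_start <= p.service_end < collection_end
    ]
    waits: dict[str, list[float]] = {"medical": [], "acute": [], "nursing1": [], "nursing2": []}
    days: list[float] = []
    n_by_type = {"medical": 0, "acute": 0, "nursing1": 0, "nursing2": 0}
    for p in visits:
        n_by_type[p.ctype] += 1
        w = p.waiting_minutes
        if w is not None:
            waits[p.ctype].append(float(w))
        if p.ctype == "medical" and p.days_to_appointment is not None:
            days.append(float(p.days_to_appointment))

    n_clinical_gps = max(1, len(profile.bookable_gps))
    n_gps = max(1, len(profile.gps))
    n_nurses = max(1, len(profile.nurses))

    total_consultations = len(visits)
    costs = compute_costs(total_consultations * factor, profile.cost_params)

    return PIReport(
        days_to_appointment=_mean(days),
        waiting_room_medical=_mean(waits["medical"]),
        waiting_room_acute=_mean(waits["acute"]),
        waiting_room_nursing1=_mean(waits["nursing1"]),
        waiting_room_nursing2=_mean(waits["nursing2"]),
        annual_consultations_per_gp=n_by_type["medical"] * factor / n_clinical_gps,
        annual_acute_per_gp=n_by_type["acute"] * factor / n_gps,
        annual_nursing_per_nurse=(n_by_type["nursing1"] + n_by_type["nursing2"]) * factor / n_nurses,
        cost_professionals=costs.professionals,
        cost_diagnostics=costs.diagnostics,
        cost_total=costs.total,
        counts={**n_by_type, "total": total_consultations},
    )


def compute_costs(annual_consultations: float, params: CostParameters) -> CostBreakdown:
    """Annual costs: per-consultation constants applied uniformly to all
    consultation types, each scaled by the sensitivity uplift."""
    if annual_consultations < 0:
        raise ValueError("consultation count must be non-negative")
    prof = annual_consultations * params.prof_cost_per_consultation * params.uplift
    diag = annual_consultations * params.diag_cost_per_consultation * params.uplift
    return CostBreakdown(professionals=prof, diagnostics=diag)


def percent_diff_raw(before: float, after: float) -> float:
    """Unrounded percentage difference of averages, 100*(after-before)/before."""
    if before == 0:
        raise ZeroDivisionError("percentage difference undefined for a zero baseline")
    return 100.0 * (after - before) / before


def percent_diff_of_averages(before: float, after: float) -> int:
    """Signed integer percentage difference, rounded half away from zero."""
    raw = percent_diff_raw(before, after)
    return int(math.copysign(math.floor(abs(raw) + 0.5), raw)) if raw else 0


def pireports_to_frame(reports: list[PIReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
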