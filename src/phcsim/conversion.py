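"""PHCC -> FHU conversion: split one centre into family-health subunits.

The conversion procedure:

1. partition the GPs into the fewest groups of six to nine, sizes as
   equal as possible, ties resolved toward a larger first group; nurses
   are partitioned likewise and paired with GP groups in order; each
   subunit gets five administrative staff;
2. discontinue the permanent acute facility — acute-dedicated GPs rejoin
   the booked-consultation pool *before* partitioning;
3. mark nursing care as scheduled;
4. switch rosters to FHU defaults (35 h/week, no administrative hours)
   and cost constants to FHU values;
5. split the source demand across subunits proportionally to their GP
   share; registered lists follow the GP share and unregistered demand is
   folded into the (now fully registered) split.

Sources with fewer than six GPs yield a single flagged undersized unit;
GP counts of 10 and 11 admit no partition into parts of 6-9 and yield a
single flagged oversized unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .kernel import WeeklyTimetable
from .profiles import FHU, PHCC, ClinicianRoster, CostParameters, UnitProfile

__all__ = ["ConversionPlan", "split_unit", "partition_sizes"]

FHU_GP_CONTRACT_HOURS = 35.0
FHU_GP_ADMIN_HOURS = 0.0
FHU_N_ADMIN = 5
MIN_UNIT, MAX_UNIT = 6, 9


class ConversionError(ValueError):
    """The source profile cannot be converted (e.g. it already is a FHU)."""


@dataclass
class ConversionPlan:
    source_unit_id: str
    fhus: list[UnitProfile]
    gp_shares: list[float]
    notes: list[str] = field(default_factory=list)

    @property
    def undersized(self) -> bool:
        return any(n.startswith("undersized") for n in self.notes)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": self.source_unit_id,
                    "fhu": f.unit_id,
                    "gps": len(f.gps),
                    "nurses": len(f.nurses),
                    "n_admin": f.n_admin,
                    "demand_share": s,
                    "daily_demand_rate": f.daily_demand_rate,
                }
                for f, s in zip(self.fhus, self.gp_shares)
            ]
        )


def partition_sizes(n: int) -> tuple[list[int], list[str]]:
    """Partition ``n`` clinicians into the fewest groups of 6-9, sizes as
    equal as possible (difference <= 1), larger groups first.

    Counts below 6 and the infeasible counts 10 and 11 (no partition into
    parts of 6-9 exists) yield a single group plus an audit note.
    """
    if n <= 0:
        raise ConversionError("cannot partition a unit with no clinicians")
    if n < MIN_UNIT:
        return [n], [f"undersized: {n} < {MIN_UNIT} clinicians, single unit kept"]
    if MIN_UNIT <= n <= MAX_UNIT:
        return [n], []
    k = math.ceil(n / MAX_UNIT)
    if MIN_UNIT * k > n:  # only n = 10, 11
        return [n], [f"oversized: no partition of {n} into groups of {MIN_UNIT}-{MAX_UNIT}"]
    base, r = divmod(n, k)
    return [base + 1] * r + [base] * (k - r), []


def _balanced_groups(n: int, k: int) -> list[int]:
    base, r = divmod(n, k)
    return [base + 1] * r + [base] * (k - r)


def split_unit(phcc: UnitProfile) -> ConversionPlan:
    """Apply the five-step conversion to one PHCC profile."""
    if phcc.model_type != PHCC:
        raise ConversionError(f"unit {phcc.unit_id!r} is already a FHU")

    notes: list[str] = []
    n_gps = len(phcc.gps)  # acute-dedicated GPs rejoin clinical work first
    gp_sizes, part_notes = partition_sizes(n_gps)
    notes.extend(part_notes)

    k = len(gp_sizes)
    nurse_sizes = _balanced_groups(len(phcc.nurses), k) if phcc.nurses else [0] * k
    if k > 1 or (not part_notes):  # proper partitions: clip nurse groups into bounds
        clipped = [min(max(s, MIN_UNIT), MAX_UNIT) for s in nurse_sizes]
        if clipped != nurse_sizes:
            notes.append(
                f"nurse groups adjusted from {nurse_sizes} to {clipped} to meet "
                f"the {MIN_UNIT}-{MAX_UNIT} bound"
            )
            nurse_sizes = clipped

    slot_gp = phcc.gps[0].slot_length if phcc.gps else 20
    slot_nurse = phcc.nurses[0].slot_length if phcc.nurses else 10
    fhu_timetable = WeeklyTimetable(
        [phcc.timetable.days[d] if d < 5 else [] for d in range(7)]
    )
    total_gps = sum(gp_sizes)
    shares = [s / total_gps for s in gp_sizes]

    fhus: list[UnitProfile] = []
    for i, (n_gp, n_nurse, share) in enumerate(zip(gp_sizes, nurse_sizes, shares), start=1):
        uid = f"{phcc.unit_id}-FHU{i}"
        gps = tuple(
            ClinicianRoster(
                clinician_id=f"{uid}-gp{j}",
                role="gp",
                weekly_contract_hours=FHU_GP_CONTRACT_HOURS,
                weekly_admin_hours=FHU_GP_ADMIN_HOURS,
                slot_length=slot_gp,
            )
            for j in range(1, n_gp + 1)
        )
        nurse_contract = phcc.nurses[0].weekly_contract_hours if phcc.nurses else 35.0
        nurse_admin = phcc.nurses[0].weekly_admin_hours if phcc.nurses else 0.0
        nurses = tuple(
            ClinicianRoster(
                clinician_id=f"{uid}-nurse{j}",
                role="nurse",
                weekly_contract_hours=nurse_contract,
                weekly_admin_hours=nurse_admin,
                slot_length=slot_nurse,
            )
            for j in range(1, n_nurse + 1)
        )
        fhus.append(
            UnitProfile(
                unit_id=uid,
                model_type=FHU,
                gps=gps,
                nurses=nurses,
                n_admin=FHU_N_ADMIN,
                timetable=fhu_timetable,
                acute_timetable=None,
                registered_patients_per_gp=phcc.registered_patients_per_gp,
                unregistered_fraction=0.0,
                daily_demand_rate=phcc.daily_demand_rate * share,
                type_profile=dict(phcc.type_profile),
                duration_specs=dict(phcc.duration_specs),
                medical_adult_fraction=phcc.medical_adult_fraction,
                reentry_prob=phcc.reentry_prob,
                reentry_delay_days=phcc.reentry_delay_days,
                cost_params=CostParameters.fhu_defaults(uplift=phcc.cost_params.uplift),
            )
        )
    return ConversionPlan(
        source_unit_id=phcc.unit_id, fhus=fhus, gp_shares=shares, notes=notes
    )
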