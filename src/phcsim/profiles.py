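"""Unit profiles: the complete parameterization of one primary-care unit.

A :class:`UnitProfile` describes either a traditional primary health care
centre (PHCC) or a family health unit (FHU): staff rosters, opening
timetables, demand level and mix, consultation-duration distributions,
follow-up re-entry behaviour, and per-consultation cost constants.
Profiles serialize to YAML/JSON-compatible dictionaries and validate
their invariants on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .kernel import DistributionSpec, SpecificationError, WeeklyTimetable

PHCC = "PHCC"
FHU = "FHU"

CONSULTATION_TYPES = ("medical", "acute", "nursing1", "nursing2")

#: Per-consultation cost constants (euro): professionals / diagnostics+drugs.
PHCC_COST_PROFESSIONALS = 13.25
PHCC_COST_DIAGNOSTICS = 39.20
FHU_COST_PROFESSIONALS = 16.32
FHU_COST_DIAGNOSTICS = 29.20


class ProfileError(ValueError):
    """A UnitProfile violates one of its invariants."""


@dataclass(frozen=True)
class CostParameters:
    """Per-consultation cost constants, with an optional sensitivity uplift."""

    prof_cost_per_consultation: float
    diag_cost_per_consultation: float
    uplift: float = 1.0

    def __post_init__(self) -> None:
        if min(self.prof_cost_per_consultation, self.diag_cost_per_consultation, self.uplift) < 0:
            raise ProfileError("cost parameters must be non-negative")

    @classmethod
    def phcc_defaults(cls, uplift: float = 1.0) -> "CostParameters":
        return cls(PHCC_COST_PROFESSIONALS, PHCC_COST_DIAGNOSTICS, uplift)

    @classmethod
    def fhu_defaults(cls, uplift: float = 1.0) -> "CostParameters":
        return cls(FHU_COST_PROFESSIONALS, FHU_COST_DIAGNOSTICS, uplift)

    def to_dict(self) -> dict:
        return {
            "prof_cost_per_consultation": self.prof_cost_per_consultation,
            "diag_cost_per_consultation": self.diag_cost_per_consultation,
            "uplift": self.uplift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostParameters":
        return cls(
            d["prof_cost_per_consultation"], d["diag_cost_per_consultation"], d.get("uplift", 1.0)
        )


@dataclass(frozen=True)
class ClinicianRoster:
    """One clinician's weekly contract.

    Clinical time is ``contract - admin`` hours; it is spread evenly over
    the unit's working days and anchored at a staggered offset within the
    unit opening hours when the executable model is built.  PHCC GPs
    default to a 42 h contract with 6 h of administrative time; FHU GPs to
    35 h fully clinical.
    """

    clinician_id: str
    role: str  # "gp" | "nurse"
    weekly_contract_hours: float
    weekly_admin_hours: float
    slot_length: int  # minutes per bookable slot
    acute_dedicated: bool = False  # PHCC only: staffs the acute facility

    def __post_init__(self) -> None:
        if self.role not in ("gp", "nurse"):
            raise ProfileError(f"unknown role {self.role!r}")
        if self.weekly_admin_hours > self.weekly_contract_hours:
            raise ProfileError("admin hours exceed contract hours")
        if self.weekly_contract_hours <= 0 or self.weekly_admin_hours < 0:
            raise ProfileError("contract hours must be positive, admin non-negative")
        if self.slot_length <= 0:
            raise ProfileError("slot_length must be positive minutes")

    @property
    def weekly_clinical_hours(self) -> float:
        return self.weekly_contract_hours - self.weekly_admin_hours

    @property
    def weekly_clinical_minutes(self) -> int:
        return int(round(self.weekly_clinical_hours * 60))

    def to_dict(self) -> dict:
        return {
            "clinician_id": self.clinician_id,
            "role": self.role,
            "weekly_contract_hours": self.weekly_contract_hours,
            "weekly_admin_hours": self.weekly_admin_hours,
            "slot_length": self.slot_length,
            "acute_dedicated": self.acute_dedicated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicianRoster":
        return cls(
            d["clinician_id"],
            d["role"],
            d["weekly_contract_hours"],
            d["weekly_admin_hours"],
            d["slot_length"],
            d.get("acute_dedicated", False),
        )


@dataclass(frozen=True)
class UnitProfile:
    """Complete parameterization of one simulated primary-care unit.

    ``daily_demand_rate`` is the expected number of *external* consultation
    requests per working day (follow-up re-entries come on top).
    ``type_profile`` maps consultation types (medical, acute, nursing1,
    nursing2) to probabilities summing to 1.  ``duration_specs`` carries a
    :class:`DistributionSpec` per consultation type; medical demand is
    split between ``medical_adult`` and ``medical_other`` specs by
    ``medical_adult_fraction``.
    """

    unit_id: str
    model_type: str  # PHCC | FHU
    gps: tuple[ClinicianRoster, ...]
    nurses: tuple[ClinicianRoster, ...]
    n_admin: int
    timetable: WeeklyTimetable
    acute_timetable: Optional[WeeklyTimetable]
    registered_patients_per_gp: int
    unregistered_fraction: float
    daily_demand_rate: float
    type_profile: dict[str, float]
    duration_specs: dict[str, DistributionSpec]
    reentry_prob: float
    reentry_delay_days: DistributionSpec
    cost_params: CostParameters
    medical_adult_fraction: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "gps", tuple(self.gps))
        object.__setattr__(self, "nurses", tuple(self.nurses))
        if self.model_type not in (PHCC, FHU):
            raise ProfileError(f"unknown model_type {self.model_type!r}")
        total = sum(self.type_profile.get(t, 0.0) for t in CONSULTATION_TYPES)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ProfileError(f"type_profile sums to {total}, expected 1")
        unknown = set(self.type_profile) - set(CONSULTATION_TYPES)
        if unknown:
            raise ProfileError(f"unknown consultation types {unknown}")
        if not 0.0 <= self.unregistered_fraction < 1.0:
            raise ProfileError("unregistered_fraction must lie in [0, 1)")
        if self.model_type == FHU:
            if self.unregistered_fraction != 0.0:
                raise ProfileError("FHU requires unregistered_fraction == 0")
            if self.acute_timetable is not None:
                raise ProfileError("FHU has no separate acute facility timetable")
            if any(r.acute_dedicated for r in self.gps):
                raise ProfileError("FHU has no acute-dedicated GPs")
        if not 0.0 <= self.reentry_prob <= 1.0:
            raise ProfileError("reentry_prob must lie in [0, 1]")
        if not 0.0 < self.medical_adult_fraction <= 1.0:
            raise ProfileError("medical_adult_fraction must lie in (0, 1]")
        if self.daily_demand_rate < 0:
            raise ProfileError("daily_demand_rate must be non-negative")
        needed = {"medical_adult", "medical_other", "acute", "nursing1", "nursing2"}
        missing = needed - set(self.duration_specs)
        if missing:
            raise ProfileError(f"duration_specs missing {sorted(missing)}")

    # -- derived staffing views ---------------------------------------
    @property
    def bookable_gps(self) -> tuple[ClinicianRoster, ...]:
        """GPs taking booked consultations (excludes PHCC acute-dedicated)."""
        return tuple(r for r in self.gps if not r.acute_dedicated)

    @property
    def acute_gps(self) -> tuple[ClinicianRoster, ...]:
        return tuple(r for r in self.gps if r.acute_dedicated)

    @property
    def registered_patients(self) -> int:
        return self.registered_patients_per_gp * len(self.gps)

    @property
    def expected_unregistered_patients(self) -> float:
        """Implied head-count of unregistered patients: with a fraction f of
        demand unregistered, the unregistered pool is f/(1-f) of the
        registered list."""
        f = self.unregistered_fraction
        return self.registered_patients * f / (1.0 - f)

    @property
    def scheduled_timetable(self) -> WeeklyTimetable:
        """Opening hours of the scheduled (non-acute) streams.

        For a PHCC with a separate acute facility, weekend opening applies
        to the acute facility only; the scheduled streams run on the
        working-day part of the unit timetable.
        """
        if self.model_type == PHCC and self.acute_timetable is not None:
            return WeeklyTimetable(
                [self.timetable.days[d] if d < 5 else [] for d in range(7)]
            )
        return self.timetable

    @property
    def effective_acute_timetable(self) -> WeeklyTimetable:
        return self.acute_timetable if self.acute_timetable is not None else self.scheduled_timetable

    def with_uplift(self, uplift: float) -> "UnitProfile":
        return replace(self, cost_params=replace(self.cost_params, uplift=uplift))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "model_type": self.model_type,
            "gps": [r.to_dict() for r in self.gps],
            "nurses": [r.to_dict() for r in self.nurses],
            "n_admin": self.n_admin,
            "timetable": self.timetable.to_dict(),
            "acute_timetable": (
                self.acute_timetable.to_dict() if self.acute_timetable is not None else None
            ),
            "registered_patients_per_gp": self.registered_patients_per_gp,
            "unregistered_fraction": self.unregistered_fraction,
            "daily_demand_rate": self.daily_demand_rate,
            "type_profile": {k: float(v) for k, v in self.type_profile.items()},
            "duration_specs": {k: v.to_dict() for k, v in self.duration_specs.items()},
            "medical_adult_fraction": self.medical_adult_fraction,
            "reentry_prob": self.reentry_prob,
            "reentry_delay_days": self.reentry_delay_days.to_dict(),
            "cost_params": self.cost_params.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitProfile":
        try:
            return cls(
                unit_id=d["unit_id"],
                model_type=d["model_type"],
                gps=tuple(ClinicianRoster.from_dict(r) for r in d["gps"]),
                nurses=tuple(ClinicianRoster.from_dict(r) for r in d["nurses"]),
                n_admin=d["n_admin"],
                timetable=WeeklyTimetable.from_dict(d["timetable"]),
                acute_timetable=(
                    WeeklyTimetable.from_dict(d["acute_timetable"])
                    if d.get("acute_timetable") is not None
                    else None
                ),
                registered_patients_per_gp=d["registered_patients_per_gp"],
                unregistered_fraction=d["unregistered_fraction"],
                daily_demand_rate=d["daily_demand_rate"],
                type_profile=dict(d["type_profile"]),
                duration_specs={
                    k: DistributionSpec.from_dict(v) for k, v in d["duration_specs"].items()
                },
                medical_adult_fraction=d.get("medical_adult_fraction", 0.8),
                reentry_prob=d["reentry_prob"],
                reentry_delay_days=DistributionSpec.from_dict(d["reentry_delay_days"]),
                cost_params=CostParameters.from_dict(d["cost_params"]),
            )
        except KeyError as exc:
            raise ProfileError(f"profile is missing required field {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "UnitProfile":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "UnitProfile":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


#: Field-level schema of the serialized profile (informal JSON-schema dialect).
PROFILE_SCHEMA: dict = {
    "unit_id": "str",
    "model_type": "PHCC | FHU",
    "gps": "list of {clinician_id, role, weekly_contract_hours, weekly_admin_hours, slot_length, acute_dedicated}",
    "nurses": "same roster structure as gps",
    "n_admin": "int, administrative staff head-count",
    "timetable": "{mon..sun: [[start_minute, end_minute], ...]}",
    "acute_timetable": "timetable or null (PHCC acute facility only)",
    "registered_patients_per_gp": "int",
    "unregistered_fraction": "float in [0,1); 0 for FHU",
    "daily_demand_rate": "float, external requests per working day",
    "type_profile": "{medical, acute, nursing1, nursing2: prob}, sums to 1",
    "duration_specs": "{medical_adult, medical_other, acute, nursing1, nursing2: {family, params}}",
    "medical_adult_fraction": "float in (0,1]",
    "reentry_prob": "float in [0,1]",
    "reentry_delay_days": "{family, params} in days",
    "cost_params": "{prof_cost_per_consultation, diag_cost_per_consultation, uplift}",
}
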