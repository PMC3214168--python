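"""Synthetic unit-profile generator.

Real unit-level inputs (activity reports of the studied units) are not
public; this module generates profiles that emulate their statistical
structure at the 2005/2007 national averages: a full-scale PHCC employs
20 GPs and 20 nurses, carries ~30,388 registered patients (~1,519 per
GP), performs ~75,000 medical consultations a year, and sees ~10% of its
demand from patients not registered with any GP.  A seeded +/-10% jitter
on demand and list size produces heterogeneous units; ``scale`` shrinks
staff and demand proportionally for fast tests.

Several parameters the source data does not pin down (consultation
durations, type mix, re-entry behaviour, nurses' consultation hours) use
illustrative defaults documented in the methods note; all are plain
profile fields and trivially overridable.
"""

from __future__ import annotations

import zlib

import numpy as np

from .kernel import DistributionSpec, WeeklyTimetable
from .profiles import FHU, PHCC, ClinicianRoster, CostParameters, UnitProfile

__all__ = ["generate_unit_profile", "generate_fixture_panel"]

#: Registered list size per GP (30,388 patients / 20 GPs).
REGISTERED_PER_GP = 1519

#: Share of demand from patients without a registered GP (PHCC).
UNREGISTERED_FRACTION = 0.10

#: Follow-up re-entry: probability and fixed delay (illustrative).
REENTRY_PROB = 0.25
REENTRY_DELAY_DAYS = 30.0

#: Consultation-type probability profile.  The acute share reflects
#: ~15,000 urgent consultations out of ~90,000 total; the remaining mass
#: splits 0.65 medical / 0.10 nursing-1 / rest nursing-2 (illustrative).
TYPE_PROFILE = {
    "medical": 0.65,
    "acute": 1.0 / 6.0,
    "nursing1": 0.10,
    "nursing2": 1.0 - 0.65 - 1.0 / 6.0 - 0.10,
}

#: External requests per working day per bookable GP, calibrated so a
#: full-scale PHCC (17 clinical GPs) performs ~75,000 medical
#: consultations a year once re-entry (x 1/(1-0.25)) is included:
#: 75000 * 0.75 / 0.65 / 260 working days / 17 GPs.
DEMAND_PER_BOOKABLE_GP_PER_DAY = 75000.0 * (1 - REENTRY_PROB) / TYPE_PROFILE["medical"] / 260.0 / 17.0

GP_SLOT_MINUTES = 20
NURSE_SLOT_MINUTES = 10

DURATION_SPECS = {
    "medical_adult": DistributionSpec.lognormal(15.0, 5.0),
    "medical_other": DistributionSpec.lognormal(15.0, 5.0),
    "acute": DistributionSpec.lognormal(12.0, 5.0),
    "nursing1": DistributionSpec.fixed(20.0),
    "nursing2": DistributionSpec.fixed(10.0),
}

#: Nurses' weekly consultation hours; the remaining contract time stands
#: for duties outside the modelled consultation streams (treatments,
#: home care, campaigns).
NURSE_CONTRACT_HOURS = 35.0
NURSE_ADMIN_HOURS = 21.0

PHCC_GP_CONTRACT_HOURS = 42.0
PHCC_GP_ADMIN_HOURS = 6.0
FHU_GP_CONTRACT_HOURS = 35.0
FHU_GP_ADMIN_HOURS = 0.0

FULL_SCALE_PHCC_GPS = 20
FULL_SCALE_PHCC_NURSES = 20
FULL_SCALE_PHCC_ACUTE_GPS = 3
FULL_SCALE_FHU_GPS = 7
FULL_SCALE_FHU_NURSES = 7
FULL_SCALE_N_ADMIN = 12
FHU_N_ADMIN = 5


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _gp_roster(uid: str, j: int, contract: float, admin: float, acute: bool = False) -> ClinicianRoster:
    return ClinicianRoster(
        clinician_id=f"{uid}-gp{j}",
        role="gp",
        weekly_contract_hours=contract,
        weekly_admin_hours=admin,
        slot_length=GP_SLOT_MINUTES,
        acute_dedicated=acute,
    )


def _nurse_roster(uid: str, j: int) -> ClinicianRoster:
    return ClinicianRoster(
        clinician_id=f"{uid}-nurse{j}",
        role="nurse",
        weekly_contract_hours=NURSE_CONTRACT_HOURS,
        weekly_admin_hours=NURSE_ADMIN_HOURS,
        slot_length=NURSE_SLOT_MINUTES,
    )


def generate_unit_profile(
    seed: int,
    model_type: str = PHCC,
    scale: float = 1.0,
    unit_id: str | None = None,
    jitter: float = 0.10,
) -> UnitProfile:
    """One reproducible synthetic unit profile.

    ``scale`` in (0, 1] shrinks staff counts and demand proportionally;
    ``jitter`` applies a seeded, mean-preserving +/- band to demand and
    list size so panels are heterogeneous.  Identical arguments always
    return identical profiles.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    rng = _rng(seed, f"unit-profile/{model_type}")
    demand_jit = 1.0 + jitter * float(rng.uniform(-1.0, 1.0))
    list_jit = 1.0 + jitter * float(rng.uniform(-1.0, 1.0))

    if model_type == PHCC:
        uid = unit_id or f"synthetic-phcc-{seed}"
        n_gps = max(1, round(FULL_SCALE_PHCC_GPS * scale))
        n_nurses = max(1, round(FULL_SCALE_PHCC_NURSES * scale))
        n_acute = min(n_gps - 1, max(1, round(FULL_SCALE_PHCC_ACUTE_GPS * scale))) if n_gps > 1 else 0
        gps = tuple(
            _gp_roster(uid, j + 1, PHCC_GP_CONTRACT_HOURS, PHCC_GP_ADMIN_HOURS,
                       acute=j >= n_gps - n_acute)
            for j in range(n_gps)
        )
        n_bookable = n_gps - n_acute
        profile = UnitProfile(
            unit_id=uid,
            model_type=PHCC,
            gps=gps,
            nurses=tuple(_nurse_roster(uid, j + 1) for j in range(n_nurses)),
            n_admin=max(1, round(FULL_SCALE_N_ADMIN * scale)),
            timetable=WeeklyTimetable.full_week(),
            acute_timetable=WeeklyTimetable.full_week(),
            registered_patients_per_gp=max(1, round(REGISTERED_PER_GP * list_jit)),
            unregistered_fraction=UNREGISTERED_FRACTION,
            daily_demand_rate=DEMAND_PER_BOOKABLE_GP_PER_DAY * n_bookable * demand_jit,
            type_profile=dict(TYPE_PROFILE),
            duration_specs=dict(DURATION_SPECS),
            reentry_prob=REENTRY_PROB,
            reentry_delay_days=DistributionSpec.fixed(REENTRY_DELAY_DAYS),
            cost_params=CostParameters.phcc_defaults(),
        )
    elif model_type == FHU:
        uid = unit_id or f"synthetic-fhu-{seed}"
        n_gps = max(1, round(FULL_SCALE_FHU_GPS * scale))
        n_nurses = max(1, round(FULL_SCALE_FHU_NURSES * scale))
        profile = UnitProfile(
            unit_id=uid,
            model_type=FHU,
            gps=tuple(
                _gp_roster(uid, j + 1, FHU_GP_CONTRACT_HOURS, FHU_GP_ADMIN_HOURS)
                for j in range(n_gps)
            ),
            nurses=tuple(_nurse_roster(uid, j + 1) for j in range(n_nurses)),
            n_admin=FHU_N_ADMIN,
            timetable=WeeklyTimetable.working_days(),
            acute_timetable=None,
            registered_patients_per_gp=max(1, round(REGISTERED_PER_GP * list_jit)),
            unregistered_fraction=0.0,
            daily_demand_rate=DEMAND_PER_BOOKABLE_GP_PER_DAY * n_gps * demand_jit,
            type_profile=dict(TYPE_PROFILE),
            duration_specs=dict(DURATION_SPECS),
            reentry_prob=REENTRY_PROB,
            reentry_delay_days=DistributionSpec.fixed(REENTRY_DELAY_DAYS),
            cost_params=CostParameters.fhu_defaults(),
        )
    else:
        raise ValueError(f"unknown model_type {model_type!r}")
    return profile


def generate_fixture_panel(
    seed: int, n_phcc: int = 13, n_fhu: int = 6, scale: float = 1.0
) -> list[UnitProfile]:
    """A reproducible panel of synthetic units (default shape 13 + 6)."""
    if n_phcc < 0 or n_fhu < 0:
        raise ValueError("panel counts must be non-negative")
    rng = _rng(seed, "fixture-panel")
    child_seeds = rng.integers(0, 2**31 - 1, size=n_phcc + n_fhu)
    panel: list[UnitProfile] = []
    for i in range(n_phcc):
        panel.append(
            generate_unit_profile(int(child_seeds[i]), PHCC, scale,
                                  unit_id=f"synthetic-phcc-{i + 1:02d}")
        )
    for i in range(n_fhu):
        panel.append(
            generate_unit_profile(int(child_seeds[n_phcc + i]), FHU, scale,
                                  unit_id=f"synthetic-fhu-{i + 1:02d}")
        )
    return panel
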