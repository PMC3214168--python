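"""Shared fixtures: reduced single-server profiles and small synthetic units.

All fixtures are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import pytest

from phcsim.kernel import DistributionSpec, WeeklyTimetable
from phcsim.profiles import ClinicianRoster, CostParameters, UnitProfile
from phcsim.synthetic import generate_unit_profile


def single_nurse_walkin_profile(
    lam_per_min: float,
    service: DistributionSpec,
    unit_id: str = "reduced",
) -> UnitProfile:
    """A PHCC stripped to one always-open nurse serving a single walk-in
    stream — the wiring used for queueing-theory oracle checks."""
    nurse = ClinicianRoster(
        clinician_id="n1", role="nurse", weekly_contract_hours=168.0,
        weekly_admin_hours=0.0, slot_length=10,
    )
    return UnitProfile(
        unit_id=unit_id,
        model_type="PHCC",
        gps=(),
        nurses=(nurse,),
        n_admin=0,
        timetable=WeeklyTimetable.always_open(),
        acute_timetable=None,
        registered_patients_per_gp=0,
        unregistered_fraction=0.0,
        daily_demand_rate=lam_per_min * 1440.0,
        type_profile={"medical": 0.0, "acute": 0.0, "nursing1": 1.0, "nursing2": 0.0},
        duration_specs={
            "medical_adult": DistributionSpec.lognormal(15, 5),
            "medical_other": DistributionSpec.lognormal(15, 5),
            "acute": DistributionSpec.lognormal(12, 5),
            "nursing1": service,
            "nursing2": DistributionSpec.fixed(10),
        },
        reentry_prob=0.0,
        reentry_delay_days=DistributionSpec.fixed(1.0),
        cost_params=CostParameters.phcc_defaults(),
    )


@pytest.fixture(scope="session")
def small_phcc() -> UnitProfile:
    return generate_unit_profile(0, "PHCC", scale=0.25)


@pytest.fixture(scope="session")
def small_fhu() -> UnitProfile:
    return generate_unit_profile(0, "FHU", scale=0.5)
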