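import dataclasses

import numpy as np
import pytest

from interkit.global_fit import fit_global
from interkit.kinetics import InjectionSchedule, RateConstants
from interkit.referencing import reference_series
from interkit.synthetic import (
    SCENARIO_CATALOG,
    SensorgramScenario,
    generate_sensorgram_series,
)


@pytest.fixture(scope="session")
def tight_binder() -> RateConstants:
    return RateConstants(k_on=4.5e4, k_off=1.03e-3, r_max=100.0, k_t=1e8)


@pytest.fixture(scope="session")
def standard_schedule() -> InjectionSchedule:
    return InjectionSchedule(t_assoc=360.0, t_dissoc=600.0, concentration=500e-9)


@pytest.fixture(scope="session")
def noisy_bundle(tight_binder):
    scen = SensorgramScenario(
        truth=tight_binder, noise_sd=0.5, drift=0.01, bulk_jump=5.0, seed=42
    )
    return generate_sensorgram_series(scen)


@pytest.fixture(scope="session")
def referenced_noisy_series(noisy_bundle):
    return reference_series(
        noisy_bundle.samples, noisy_bundle.blank, noisy_bundle.empty_surface
    )


@pytest.fixture(scope="session")
def noiseless_series(tight_binder):
    scen = SensorgramScenario(truth=tight_binder, noise_sd=0.0, seed=0)
    b = generate_sensorgram_series(scen)
    return reference_series(b.samples, b.blank, b.empty_surface)


@pytest.fixture(scope="session")
def fitted_noisy(referenced_noisy_series):
    return fit_global(referenced_noisy_series)


@pytest.fixture(scope="session")
def catalog_scenario():
    return SCENARIO_CATALOG["FL1-MPP1"]
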