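import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from photofret import (
    DrugEffectProfile,
    SensorKineticsParams,
    SessionSchedule,
    SimulatedCohortSpec,
    TreatmentArm,
)


@pytest.fixture
def default_params():
    return SensorKineticsParams()


@pytest.fixture
def clean_params():
    """Kinetics with every non-kinetic corruption switched off."""
    return SensorKineticsParams(noise_sd=0.0, bleach_rate=0.0)


@pytest.fixture
def mini_schedule():
    """A scaled-down session (5 s dark lead-in + 10 s interleaved at 10 fps)
    for unit tests that do not care about the full one-minute window."""
    return SessionSchedule(hours=(0.0, 1.0, 2.0, 3.0), off_lead_s=5.0, interleaved_s=10.0)


@pytest.fixture
def vehicle_arm():
    return TreatmentArm("vehicle", DrugEffectProfile("vehicle"), dose=0.0, route="s.c.")


@pytest.fixture
def inhibitor_arm():
    return TreatmentArm(
        "inhibitor", DrugEffectProfile("inhibitor", magnitude=0.25), dose=2.0, route="s.c."
    )


@pytest.fixture
def small_cohort_spec(vehicle_arm, inhibitor_arm):
    return SimulatedCohortSpec(
        n_animals=3, treatments=(vehicle_arm, inhibitor_arm), jitter_cv=0.2, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
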