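import pytest
from hypothesis import HealthCheck, settings

from exobia import Facility, PersonnelRole, Strategy, fixtures

# fixtures drawn inside hypothesis tests are read-only domain objects
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_bundle():
    """Packaged base case: (strategies, facilities, mixes)."""
    return fixtures.load_base_config()


@pytest.fixture(scope="session")
def base_models():
    """One fully specified BiaModel per fixture facility."""
    return fixtures.all_base_models()


@pytest.fixture(scope="session")
def model_a(base_models):
    return base_models["A"]


@pytest.fixture
def simple_facility():
    """A minimal hand-built facility for arithmetic oracles."""
    return Facility(
        label="X",
        structure="IRF",
        users_per_year=100,
        sessions_per_user=20,
        wage_table={"physical_therapist": 45.0, "exercise_specialist": 35.0, "aide": 25.0},
        capacity_sessions_per_year=2000,
        adoption_rate=0.5,
    )


@pytest.fixture
def exo_strategy():
    """An exoskeleton-like strategy: $150k device, 5-yr life, $10k/yr upkeep."""
    return Strategy(
        name="RT_exo",
        device_cost=150_000,
        maintenance_annual=10_000,
        maintenance_contract_years=5,
        lifespan_years=5,
        personnel=(
            PersonnelRole("physical_therapist", 1),
            PersonnelRole("aide", 1),
        ),
        training_hours_per_clinician=18,
        trainees_per_site=2,
    )
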