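"""Unit and property tests for the per-strategy cost equations."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from exobia import (
    ConfigurationError,
    Facility,
    InvalidInputError,
    PersonnelRole,
    Strategy,
    ValidationError,
    annual_equivalent_device_cost,
    annualized_training_cost,
    per_session_device_cost,
    per_session_personnel_cost,
    strategy_annual_cost,
)


def make_strategy(**kw):
    defaults = dict(name="S", lifespan_years=5)
    defaults.update(kw)
    return Strategy(**defaults)


class TestAnnualEquivalentDeviceCost:
    @pytest.mark.parametrize(
        "device, maint, contract, life, expected",
        [
            # exoskeleton: $150k over 5 yr plus $10k/yr upkeep -> $40k/yr
            (150_000, 10_000, 5, 5, 40_000),
            (0, 0, 0, 5, 0),
            # high-cost overground: 5-yr contract spread over a 20-yr life
            (225_000, 7_500, 5, 20, 13_125),
        ],
    )
    def test_straight_line_amortization(self, device, maint, contract, life, expected):
        s = make_strategy(
            device_cost=device,
            maintenance_annual=maint,
            maintenance_contract_years=contract,
            lifespan_years=life,
        )
        assert annual_equivalent_device_cost(s) == pytest.approx(expected)

    def test_nonpositive_lifespan_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            make_strategy(lifespan_years=0)

    def test_device_free_strategy_costs_nothing(self):
        s = make_strategy(device_cost=50_000, device_free=True)
        assert annual_equivalent_device_cost(s) == 0.0

    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        device=st.floats(min_value=0, max_value=1e6),
        maint=st.floats(min_value=0, max_value=1e5),
    )
    def test_homogeneous_degree_one_in_costs(self, scale, device, maint):
        base = make_strategy(
            device_cost=device, maintenance_annual=maint, maintenance_contract_years=3
        )
        scaled = make_strategy(
            device_cost=device * scale,
            maintenance_annual=maint * scale,
            maintenance_contract_years=3,
        )
        assert annual_equivalent_device_cost(scaled) == pytest.approx(
            scale * annual_equivalent_device_cost(base), rel=1e-9
        )


class TestPerSessionDeviceCost:
    def test_fixed_cost_spread_over_adopted_capacity(self, simple_facility, exo_strategy):
        # $40k/yr over 2000 x 0.5 = 1000 billable sessions
        assert per_session_device_cost(exo_strategy, simple_facility) == pytest.approx(40.0)

    def test_full_adoption_halves_unit_cost(self, simple_facility, exo_strategy):
        full = Facility(
            label="X",
            structure="IRF",
            users_per_year=100,
            sessions_per_user=20,
            wage_table=dict(simple_facility.wage_table),
            capacity_sessions_per_year=2000,
            adoption_rate=1.0,
        )
        assert per_session_device_cost(exo_strategy, full) == pytest.approx(20.0)

    def test_zero_annual_equivalent_gives_zero(self, simple_facility):
        assert per_session_device_cost(make_strategy(), simple_facility) == 0.0

    def test_invalid_capacity_or_adoption_rejected(self, exo_strategy, simple_facility):
        with pytest.raises(ValidationError):
            Facility(
                label="X", structure="IRF", users_per_year=1, sessions_per_user=1,
                wage_table={"physical_therapist": 45.0}, capacity_sessions_per_year=0,
            )
        with pytest.raises(ValidationError):
            Facility(
                label="X", structure="IRF", users_per_year=1, sessions_per_user=1,
                wage_table={"physical_therapist": 45.0}, adoption_rate=0.0,
            )
        bad = Facility(
            label="X", structure="IRF", users_per_year=1, sessions_per_user=1,
            wage_table={"physical_therapist": 45.0},
        )
        object.__setattr__(bad, "capacity_sessions_per_year", 0.0)
        with pytest.raises(InvalidInputError):
            per_session_device_cost(exo_strategy, bad)

    @given(
        adoption=st.floats(min_value=0.05, max_value=0.95),
        bump=st.floats(min_value=0.01, max_value=0.05),
    )
    def test_strictly_decreasing_in_adoption(self, simple_facility, adoption, bump):
        s = make_strategy(device_cost=100_000)
        lo = Facility(
            label="X", structure="IRF", users_per_year=1, sessions_per_user=1,
            wage_table={"physical_therapist": 45.0}, adoption_rate=adoption,
        )
        hi = Facility(
            label="X", structure="IRF", users_per_year=1, sessions_per_user=1,
            wage_table={"physical_therapist": 45.0}, adoption_rate=adoption + bump,
        )
        assert per_session_device_cost(s, hi) < per_session_device_cost(s, lo)


class TestPerSessionPersonnelCost:
    def test_sums_heads_times_wage_times_duration(self, simple_facility):
        s = make_strategy(
            personnel=(PersonnelRole("physical_therapist", 1), PersonnelRole("aide", 1))
        )
        assert per_session_personnel_cost(s, simple_facility) == pytest.approx(70.0)

    def test_empty_roster_costs_nothing(self, simple_facility):
        assert per_session_personnel_cost(make_strategy(), simple_facility) == 0.0

    def test_treadmill_style_roster(self, simple_facility):
        # 1 PT + 1 exercise specialist + 2 aides at $45/$35/$25 for one hour
        s = make_strategy(
            personnel=(
                PersonnelRole("physical_therapist", 1),
                PersonnelRole("exercise_specialist", 1),
                PersonnelRole("aide", 2),
            )
        )
        assert per_session_personnel_cost(s, simple_facility) == pytest.approx(130.0)

    def test_missing_wage_error_names_the_role(self, simple_facility):
        s = make_strategy(personnel=(PersonnelRole("hydrotherapist", 1),))
        with pytest.raises(ConfigurationError, match="hydrotherapist"):
            per_session_personnel_cost(s, simple_facility)

    def test_role_level_wage_override_beats_facility_table(self, simple_facility):
        s = make_strategy(personnel=(PersonnelRole("physical_therapist", 1, hourly_wage=60.0),))
        assert per_session_personnel_cost(s, simple_facility) == pytest.approx(60.0)


class TestAnnualizedTrainingCost:
    @pytest.mark.parametrize(
        "hours, trainees, life, expected",
        [
            (18, 2, 5, 324.0),  # 2 x 18 h at the $45 PT wage over 5 years
            (0, 2, 5, 0.0),
            (1, 2, 5, 18.0),
        ],
    )
    def test_pt_wage_amortized_over_lifespan(
        self, simple_facility, hours, trainees, life, expected
    ):
        s = make_strategy(
            training_hours_per_clinician=hours, trainees_per_site=trainees, lifespan_years=life
        )
        assert annualized_training_cost(s, simple_facility) == pytest.approx(expected)


class TestStrategyAnnualCost:
    def test_no_sessions_no_cost(self, simple_facility, exo_strategy):
        b = strategy_annual_cost(exo_strategy, simple_facility, 0)
        assert b.total == 0.0
        assert b.training_component == 0.0

    def test_composite_total(self, simple_facility, exo_strategy):
        # 100 sessions x ($70 personnel + $40 device) + $324 training
        b = strategy_annual_cost(exo_strategy, simple_facility, 100)
        assert b.total == pytest.approx(11_324.0)
        assert b.personnel_component == pytest.approx(7_000.0)
        assert b.device_component + b.maintenance_component == pytest.approx(4_000.0)
        assert b.training_component == pytest.approx(324.0)

    def test_device_maintenance_split_matches_annual_equivalent_shares(
        self, simple_facility, exo_strategy
    ):
        # exoskeleton annual equivalent is $30k purchase + $10k maintenance
        b = strategy_annual_cost(exo_strategy, simple_facility, 100)
        assert b.device_component == pytest.approx(3_000.0)
        assert b.maintenance_component == pytest.approx(1_000.0)

    def test_negative_sessions_rejected(self, simple_facility, exo_strategy):
        with pytest.raises(InvalidInputError):
            strategy_annual_cost(exo_strategy, simple_facility, -1)

    def test_affine_in_session_count(self, simple_facility, exo_strategy):
        """cost(n) = training + n x (per-session personnel + device), n = 0..50."""
        per_session = 70.0 + 40.0
        training = 324.0
        for n in range(0, 51):
            b = strategy_annual_cost(exo_strategy, simple_facility, n)
            expected = (training if n > 0 else 0.0) + n * per_session
            assert b.total == pytest.approx(expected)

    @given(n=st.integers(min_value=1, max_value=10_000))
    def test_components_nonnegative_and_sum_to_total(self, simple_facility, exo_strategy, n):
        b = strategy_annual_cost(exo_strategy, simple_facility, n)
        parts = (
            b.device_component,
            b.maintenance_component,
            b.training_component,
            b.personnel_component,
        )
        assert all(p >= 0 for p in parts)
        assert b.total == pytest.approx(sum(parts), abs=1.0)

    def test_doubling_sessions_doubles_variable_components(self, simple_facility, exo_strategy):
        b1 = strategy_annual_cost(exo_strategy, simple_facility, 37)
        b2 = strategy_annual_cost(exo_strategy, simple_facility, 74)
        assert b2.personnel_component == pytest.approx(2 * b1.personnel_component)
        assert b2.device_component == pytest.approx(2 * b1.device_component)
        assert b2.maintenance_component == pytest.approx(2 * b1.maintenance_component)
        assert b2.training_component == b1.training_component
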