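"""Tests for session allocation, substitution, and net budget impact."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from exobia import (
    BiaModel,
    ConfigurationError,
    Facility,
    InvalidSubstitutionError,
    MarketShareMix,
    PersonnelRole,
    Strategy,
    ValidationError,
    allocate_sessions,
    apply_substitution,
    budget_impact,
    per_session_total_cost,
    sessions_per_year,
    strategy_annual_cost,
)
from exobia.bia_engine import largest_remainder, round_half_up


class TestSessionVolume:
    def test_users_times_sessions(self, base_bundle):
        _, facilities, _ = base_bundle
        assert sessions_per_year(facilities["A"]) == 2752
        assert sessions_per_year(facilities["C"]) == 2256

    def test_zero_users(self, simple_facility):
        f = Facility(
            label="Z", structure="LTCH", users_per_year=0, sessions_per_user=16,
            wage_table={"physical_therapist": 45.0},
        )
        assert sessions_per_year(f) == 0

    def test_canonical_total_overrides_product(self, base_bundle):
        # facility D's source table prints 3105 although 155 x 20 = 3100
        _, facilities, _ = base_bundle
        assert facilities["D"].users_per_year * facilities["D"].sessions_per_user == 3100
        assert sessions_per_year(facilities["D"]) == 3105


class TestRounding:
    @pytest.mark.parametrize("x, expected", [(310.5, 311), (198.4, 198), (908.16, 908),
                                             (0.5, 1), (1.5, 2), (2.49999, 2)])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected

    def test_largest_remainder_sums_exactly(self):
        out = largest_remainder(100, {"a": 1.0, "b": 1.0, "c": 1.0})
        assert sum(out.values()) == 100
        assert sorted(out.values()) == [33, 33, 34]


class TestAllocateSessions:
    def test_shares_rounded_half_up(self):
        mix = MarketShareMix(shares={"BWSTT": 0.33, "OGT_low": 0.67})
        assert allocate_sessions(2752, mix)["BWSTT"] == 908

    def test_ten_percent_of_odd_total_rounds_up(self):
        mix = MarketShareMix(shares={"RT_exo": 0.10, "OGT_low": 0.90})
        assert allocate_sessions(3105, mix)["RT_exo"] == 311

    def test_zero_total_gives_zeros(self):
        mix = MarketShareMix(shares={"a": 0.5, "b": 0.5})
        assert allocate_sessions(0, mix) == {"a": 0, "b": 0}

    def test_canonical_counts_returned_unchanged(self):
        mix = MarketShareMix(
            shares={"a": 0.5, "b": 0.5}, session_counts={"a": 7, "b": 13}
        )
        assert allocate_sessions(1000, mix) == {"a": 7, "b": 13}

    def test_shares_off_simplex_rejected(self):
        with pytest.raises(ValidationError):
            MarketShareMix(shares={"a": 0.5, "b": 0.4})
        with pytest.raises(ValidationError):
            MarketShareMix(shares={"a": -0.1, "b": 1.1})

    def test_inconsistent_counts_warn_not_error(self, base_bundle):
        # facility B future counts sum to 3888, not 3968: flagged, kept
        _, _, mixes = base_bundle
        mix = mixes[("B", "future")]
        with pytest.warns(UserWarning, match="3888"):
            mix.check_counts_total(3968, context="B future")


class TestApplySubstitution:
    def test_reported_facility_a_substitution(self, base_bundle):
        _, _, mixes = base_bundle
        current = mixes[("A", "current")]
        future = apply_substitution(
            current,
            {"BWSTT": 27, "stationary_robotic": 137, "OGT_low": 111},
            "RT_exo",
        )
        assert future.session_counts == {
            "BWSTT": 881, "stationary_robotic": 303, "OGT_low": 1293, "RT_exo": 275,
        }

    def test_empty_substitution_is_identity(self, base_bundle):
        _, _, mixes = base_bundle
        current = mixes[("A", "current")]
        future = apply_substitution(current, {}, "RT_exo", new_sessions=0)
        for name, c in current.session_counts.items():
            assert future.session_counts[name] == c

    def test_printed_recipient_count_absorbs_rounding(self, base_bundle):
        # facility C donors sum to 224 but the printed exoskeleton count is 226
        _, _, mixes = base_bundle
        current = mixes[("C", "current")]
        future = apply_substitution(
            current,
            {"BWSTT": 90, "stationary_robotic": 67, "OGT_low": 67},
            "RT_exo",
            new_sessions=226,
        )
        total = sum(future.session_counts.values())
        assert abs(total - 2256) <= len(future.session_counts)

    def test_over_donation_rejected(self, base_bundle):
        _, _, mixes = base_bundle
        with pytest.raises(InvalidSubstitutionError):
            apply_substitution(mixes[("A", "current")], {"BWSTT": 10_000}, "RT_exo")

    def test_unbalanced_recipient_count_rejected(self, base_bundle):
        _, _, mixes = base_bundle
        with pytest.raises(InvalidSubstitutionError):
            apply_substitution(
                mixes[("A", "current")], {"BWSTT": 10}, "RT_exo", new_sessions=100
            )

    @given(
        counts=st.lists(st.integers(min_value=5, max_value=500), min_size=2, max_size=4),
        data=st.data(),
    )
    def test_sessions_conserved(self, counts, data):
        names = [f"s{i}" for i in range(len(counts))]
        current = MarketShareMix.from_counts(dict(zip(names, counts)))
        donation = {
            n: data.draw(st.integers(min_value=0, max_value=c), label=n)
            for n, c in zip(names, counts)
        }
        future = apply_substitution(current, donation, "new")
        assert sum(future.session_counts.values()) == sum(counts)


def _tiny_model(wages=None, counts=(60, 40)):
    facility = Facility(
        label="T", structure="IRF", users_per_year=10, sessions_per_user=10,
        wage_table=wages or {"physical_therapist": 45.0, "aide": 25.0},
    )
    strategies = {
        "cheap": Strategy(
            name="cheap", device_cost=10_000, lifespan_years=10,
            personnel=(PersonnelRole("physical_therapist", 1),),
        ),
        "dear": Strategy(
            name="dear", device_cost=100_000, lifespan_years=5,
            personnel=(PersonnelRole("physical_therapist", 1), PersonnelRole("aide", 2)),
        ),
    }
    current = MarketShareMix.from_counts({"cheap": counts[0], "dear": counts[1]})
    return facility, strategies, current


class TestBudgetImpact:
    def test_null_substitution_is_exactly_zero(self, base_models):
        for model in base_models.values():
            null = BiaModel(
                facility=model.facility,
                strategies=model.strategies,
                current=model.current,
                future=model.current,
            )
            assert null.evaluate().net_difference == 0.0

    def test_antisymmetry(self, model_a):
        forward = model_a.evaluate()
        backward = budget_impact(
            model_a.facility, model_a.strategies, model_a.future, model_a.current
        )
        assert backward.net_difference == pytest.approx(-forward.net_difference)

    def test_strategy_missing_from_set_is_configuration_error(self):
        facility, strategies, current = _tiny_model()
        future = apply_substitution(current, {"cheap": 10}, "mystery")
        with pytest.raises(ConfigurationError, match="mystery"):
            budget_impact(facility, strategies, current, future)

    def test_totals_match_breakdowns(self, base_models):
        res = base_models["C"].evaluate()
        assert res.current_total == pytest.approx(
            sum(b.total for b in res.current_breakdowns.values())
        )
        assert res.net_difference == res.future_total - res.current_total

    def test_facility_specific_roster_override_applied(self, base_models):
        # facility C staffs BWSTT with 1 PT + 3 exercise specialists
        res = base_models["C"].evaluate()
        wage = base_models["C"].facility.wage_table
        expected = wage["physical_therapist"] + 3 * wage["exercise_specialist"]
        b = res.current_breakdowns["BWSTT"]
        assert b.personnel_component == pytest.approx(b.n_sessions * expected)

    @given(
        k=st.integers(min_value=0, max_value=40),
        n_i=st.integers(min_value=40, max_value=100),
        n_j=st.integers(min_value=0, max_value=100),
    )
    def test_exchange_property_matches_enumeration(self, k, n_i, n_j):
        """Moving k sessions between strategies changes total cost by
        k x (per-session cost difference) plus any training step."""
        facility, strategies, _ = _tiny_model()
        facility = Facility(
            label="T", structure="IRF", users_per_year=1, sessions_per_user=1,
            wage_table=dict(facility.wage_table), annual_sessions=n_i + n_j + 1,
        )
        current = MarketShareMix.from_counts({"cheap": n_i, "dear": n_j + 1})
        future = apply_substitution(current, {"cheap": k}, "dear")
        res = budget_impact(facility, strategies, current, future)
        # independent brute-force recomputation
        def world_cost(counts):
            return sum(
                strategy_annual_cost(strategies[n], facility, c).total
                for n, c in counts.items()
            )
        brute = world_cost(future.session_counts) - world_cost(current.session_counts)
        assert res.net_difference == pytest.approx(brute, abs=1e-6)
        delta = per_session_total_cost(strategies["dear"], facility) - per_session_total_cost(
            strategies["cheap"], facility
        )
        training_step = 0.0
        if n_i - k == 0 and n_i > 0:  # cheap drops out of the portfolio
            from exobia import annualized_training_cost
            training_step = -annualized_training_cost(strategies["cheap"], facility)
        assert res.net_difference == pytest.approx(k * delta + training_step, abs=1e-6)

    def test_session_conservation_between_worlds(self, base_models):
        for label, model in base_models.items():
            if label == "B":  # counts shipped as printed, known inconsistency
                continue
            cur = sum(model.current_counts().values())
            fut = sum(model.future_counts().values())
            assert abs(cur - fut) <= len(model.future_counts())
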