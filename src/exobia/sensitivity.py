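"""One-way, scenario, and probabilistic sensitivity analysis.

The base case carries several structural assumptions — exoskeleton price,
clinician adoption, which conventional strategies donate sessions, device
life — whose uncertainty dominates the (small) base-case savings. Three
standard decision-analytic probes are provided:

* :func:`one_way_sensitivity` — vary a single input across a grid,
  holding everything else at base (tornado analysis);
* :func:`scenario_shift` — instead of introducing the exoskeleton, shift
  market share toward one conventional strategy;
* :func:`run_psa` — seeded Monte Carlo over wages, device cost, and the
  substitution mix simultaneously.

PSA draws are consumed in a documented fixed order (wages by sorted role
name, then device-cost multiplier, then substitution weights) so results
are reproducible bit-for-bit for a given seed and spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bia_engine import (
    BiaModel,
    BudgetImpactResult,
    InvalidSubstitutionError,
    MarketShareMix,
    apply_substitution,
    largest_remainder,
    round_half_up,
)
from .model_core import (
    Facility,
    InvalidInputError,
    ConfigurationError,
    ModelError,
    ValidationError,
    per_session_total_cost,
)

__all__ = [
    "OWSA_PARAMETERS",
    "OWSAParameter",
    "PSASpec",
    "PSAResult",
    "InvalidScenarioError",
    "one_way_sensitivity",
    "scenario_shift",
    "run_psa",
    "default_distributions",
]

#: Supported one-way parameters and their base-case spans
#: (device cost 50–200%, adoption 10–100%, donor policy, device life 3–8 yr).
OWSA_PARAMETERS = (
    "rt_exo_device_cost_multiplier",
    "rt_exo_adoption_rate",
    "substituted_strategy_policy",
    "rt_exo_lifespan_years",
)

_CATEGORICAL = {"substituted_strategy_policy"}


class InvalidScenarioError(ValidationError):
    """A scenario shift is infeasible (share out of [0, 1] or donors exhausted)."""


@dataclass(frozen=True)
class OWSAParameter:
    """One input varied in a one-way sensitivity analysis."""

    name: str
    low_value: object
    high_value: object
    base_value: object

    def __post_init__(self) -> None:
        if self.name not in OWSA_PARAMETERS:
            raise ConfigurationError(
                f"unknown one-way parameter {self.name!r}; expected one of {OWSA_PARAMETERS}"
            )
        if self.low_value == self.high_value:
            raise ValidationError(f"parameter {self.name!r}: low and high must differ")


def _policy_future_mix(model: BiaModel, policy: str) -> MarketShareMix:
    """Rebuild the future mix under a donor-selection policy.

    ``highest_cost`` (``lowest_cost``) takes the exoskeleton's sessions
    from the most (least) expensive conventional strategy per session,
    spilling over to the next-ranked donor if the first runs dry.
    ``base`` keeps the base-case substitution.
    """
    if policy == "base":
        return model.future
    if policy not in ("highest_cost", "lowest_cost"):
        raise ConfigurationError(
            f"unknown substitution policy {policy!r}; "
            "expected 'base', 'highest_cost' or 'lowest_cost'"
        )
    counts = model.current_counts()
    resolved = model.facility.resolve_strategies(model.strategies)
    donors = [n for n, c in counts.items() if n != model.new_strategy and c > 0]
    if not donors:
        raise InvalidScenarioError("no donor strategies with sessions available")
    ranked = sorted(
        donors,
        key=lambda n: per_session_total_cost(resolved[n], model.facility),
        reverse=(policy == "highest_cost"),
    )
    needed = model.new_strategy_sessions()
    substitution: dict[str, int] = {}
    for donor in ranked:
        take = min(needed, counts[donor])
        if take:
            substitution[donor] = take
            needed -= take
        if needed == 0:
            break
    if needed:
        raise InvalidScenarioError(
            f"donors cannot supply {model.new_strategy_sessions()} sessions"
        )
    return apply_substitution(model.current, substitution, model.new_strategy)


def _apply_parameter(model: BiaModel, name: str, value) -> BiaModel:
    """Return a copy of the model with one input set to ``value``."""
    if name == "rt_exo_device_cost_multiplier":
        m = float(value)
        if m <= 0:
            raise InvalidInputError(f"device-cost multiplier must be > 0, got {m}")
        strategies = dict(model.strategies)
        rt = strategies[model.new_strategy]
        strategies[model.new_strategy] = replace(rt, device_cost=rt.device_cost * m)
        return model.with_(strategies=strategies)
    if name == "rt_exo_adoption_rate":
        a = float(value)
        if not (0 < a <= 1):
            raise InvalidInputError(f"adoption rate must be in (0, 1], got {a}")
        overrides = dict(model.facility.adoption_overrides)
        overrides[model.new_strategy] = a
        return model.with_(facility=replace(model.facility, adoption_overrides=overrides))
    if name == "rt_exo_lifespan_years":
        life = float(value)
        if life <= 0:
            raise InvalidInputError(f"lifespan must be > 0, got {life}")
        strategies = dict(model.strategies)
        rt = strategies[model.new_strategy]
        # maintenance is a running annual charge: the contract tracks the life
        strategies[model.new_strategy] = replace(
            rt, lifespan_years=life, maintenance_contract_years=life
        )
        return model.with_(strategies=strategies)
    if name == "substituted_strategy_policy":
        return model.with_(future=_policy_future_mix(model, str(value)))
    raise ConfigurationError(f"unknown one-way parameter {name!r}")


def one_way_sensitivity(
    model: BiaModel, parameter: OWSAParameter, grid_points: int = 9
) -> list[tuple[object, float]]:
    """Net budget impact across a grid of one parameter's values.

    Numeric parameters use ``grid_points`` evenly spaced values from low
    to high, with the base value inserted if absent; the categorical
    donor policy evaluates each named policy. Values outside the model's
    valid range are skipped with a warning.
    """
    if parameter.name in _CATEGORICAL:
        grid: Sequence[object] = list(
            dict.fromkeys([parameter.low_value, parameter.base_value, parameter.high_value])
        )
    else:
        lo, hi = float(parameter.low_value), float(parameter.high_value)
        values = np.linspace(lo, hi, grid_points)
        base = float(parameter.base_value)
        grid = sorted(set(np.append(values, base).tolist()))
    results: list[tuple[object, float]] = []
    for value in grid:
        try:
            perturbed = _apply_parameter(model, parameter.name, value)
        except InvalidInputError as exc:
            warnings.warn(f"skipping {parameter.name}={value!r}: {exc}", stacklevel=2)
            continue
        results.append((value, perturbed.evaluate().net_difference))
    return results


def scenario_shift(
    model: BiaModel,
    recipient_strategy: str,
    shift_fraction: float = 0.10,
    donors: Mapping[str, int] | None = None,
) -> BudgetImpactResult:
    """Shift market share toward one conventional strategy, no exoskeleton.

    The recipient's share rises by ``shift_fraction`` of total sessions;
    donors give up sessions proportionally to their current counts unless
    an explicit donor vector is supplied. Returns the budget impact of
    the shifted world relative to the current one.
    """
    if not (0 <= shift_fraction <= 1):
        raise InvalidScenarioError(f"shift_fraction must be in [0, 1], got {shift_fraction}")
    counts = model.current_counts()
    if recipient_strategy not in counts:
        raise ConfigurationError(
            f"recipient strategy {recipient_strategy!r} not offered at "
            f"facility {model.facility.label!r}"
        )
    current = MarketShareMix.from_counts(counts) if sum(counts.values()) else model.current
    total = sum(counts.values())
    shift_n = round_half_up(shift_fraction * total)
    if shift_n == 0:
        future = current
    else:
        donor_counts = {n: c for n, c in counts.items() if n != recipient_strategy and c > 0}
        if donors is not None:
            substitution = {n: int(d) for n, d in donors.items()}
        else:
            if shift_n > sum(donor_counts.values()):
                raise InvalidScenarioError(
                    f"cannot shift {shift_n} sessions: donors only hold "
                    f"{sum(donor_counts.values())}"
                )
            substitution = largest_remainder(shift_n, donor_counts)
        for donor, d in substitution.items():
            if d > counts.get(donor, 0):
                raise InvalidScenarioError(
                    f"donor {donor!r} cannot give up {d} of {counts.get(donor, 0)} sessions"
                )
        future = apply_substitution(current, substitution, recipient_strategy)
        if future.shares[recipient_strategy] > 1 + 1e-12:
            raise InvalidScenarioError("recipient share would exceed 1")
    shifted = model.with_(current=current, future=future, new_strategy=recipient_strategy)
    return shifted.evaluate()


def default_distributions() -> dict[str, dict]:
    """Default PSA parameter distributions.

    * wages: gamma per role, mean = base wage, coefficient of variation 0.2;
    * device cost: uniform multiplier on the exoskeleton price, ±50%;
    * substitution: Dirichlet over donor weights, concentration 10 at the
      base donation proportions.

    These are modelling defaults, configurable per run.
    """
    return {
        "wages": {"family": "gamma", "cv": 0.2},
        "device_cost": {"family": "uniform", "low": 0.5, "high": 1.5},
        "substitution": {"family": "dirichlet", "concentration": 10.0},
    }


@dataclass(frozen=True)
class PSASpec:
    """Specification of a probabilistic sensitivity analysis run."""

    n_draws: int
    seed: int
    distributions: Mapping[str, Mapping] = field(default_factory=default_distributions)

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValidationError(f"n_draws must be >= 1, got {self.n_draws}")
        dists = {k: dict(v) for k, v in dict(self.distributions).items()}
        merged = default_distributions()
        merged.update(dists)
        unknown = set(merged) - {"wages", "device_cost", "substitution"}
        if unknown:
            raise ConfigurationError(f"unknown PSA distribution keys: {sorted(unknown)}")
        object.__setattr__(self, "distributions", merged)


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo distribution of the net budget impact (USD/yr)."""

    net_differences: np.ndarray
    mean: float
    percentile_2_5: float
    percentile_97_5: float
    probability_of_savings: float
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.percentile_2_5 > self.percentile_97_5:
            raise ValidationError("PSA percentiles out of order")
        if not (0 <= self.probability_of_savings <= 1):
            raise ValidationError("probability of savings must be in [0, 1]")

    @classmethod
    def from_draws(cls, draws: np.ndarray, n_rejected: int = 0) -> "PSAResult":
        draws = np.asarray(draws, dtype=float)
        return cls(
            net_differences=draws,
            mean=float(draws.mean()),
            percentile_2_5=float(np.percentile(draws, 2.5)),
            percentile_97_5=float(np.percentile(draws, 97.5)),
            probability_of_savings=float(np.mean(draws < 0)),
            n_rejected=n_rejected,
        )


def _draw_wages(rng: np.random.Generator, facility: Facility, spec: Mapping) -> dict[str, float]:
    family = spec.get("family", "gamma")
    wages = {}
    for role in sorted(facility.wage_table):  # fixed draw order
        base = facility.wage_table[role]
        if family == "point":
            wages[role] = base
        elif family == "gamma":
            cv = float(spec.get("cv", 0.2))
            shape = 1.0 / cv**2
            wages[role] = float(rng.gamma(shape, base * cv**2))
        elif family == "two_point":
            delta = float(spec.get("delta", 0.0))
            wages[role] = base + (delta if rng.random() < 0.5 else -delta)
        else:
            raise ConfigurationError(f"unknown wage distribution family {family!r}")
    return wages


def _draw_device_multiplier(rng: np.random.Generator, spec: Mapping) -> float:
    family = spec.get("family", "uniform")
    if family == "point":
        return 1.0
    if family == "uniform":
        return float(rng.uniform(float(spec.get("low", 0.5)), float(spec.get("high", 1.5))))
    raise ConfigurationError(f"unknown device-cost distribution family {family!r}")


def _draw_substitution(
    rng: np.random.Generator, model: BiaModel, spec: Mapping
) -> Mapping[str, int] | None:
    """Draw a donor substitution vector; ``None`` keeps the base future mix."""
    family = spec.get("family", "dirichlet")
    if family == "point":
        return None
    if family != "dirichlet":
        raise ConfigurationError(f"unknown substitution distribution family {family!r}")
    base = model.donation_vector()
    if not base:
        return None
    conc = float(spec.get("concentration", 10.0))
    names = sorted(base)  # fixed draw order
    base_w = np.array([base[n] for n in names], dtype=float)
    alpha = conc * base_w / base_w.sum()
    w = rng.dirichlet(alpha)
    return largest_remainder(
        model.new_strategy_sessions(), dict(zip(names, w.tolist()))
    )


def run_psa(model: BiaModel, spec: PSASpec) -> PSAResult:
    """Propagate joint input uncertainty to the net budget impact.

    Each draw independently samples wages, the exoskeleton device cost,
    and the substitution vector, rebuilds the model, and re-evaluates the
    budget impact. Draws that land outside the model's valid domain
    (e.g. a nonpositive wage, or a substitution a donor cannot supply)
    are rejected and redrawn; the rejection count is reported.
    """
    rng = np.random.default_rng(spec.seed)
    dists = spec.distributions
    draws = np.empty(spec.n_draws, dtype=float)
    n_rejected = 0
    max_rejections = 1000 + 10 * spec.n_draws
    i = 0
    while i < spec.n_draws:
        try:
            wages = _draw_wages(rng, model.facility, dists["wages"])
            if any(w <= 0 for w in wages.values()):
                raise InvalidInputError("drawn wage is nonpositive")
            mult = _draw_device_multiplier(rng, dists["device_cost"])
            substitution = _draw_substitution(rng, model, dists["substitution"])
            perturbed = model.with_(
                facility=replace(model.facility, wage_table=wages)
            )
            perturbed = _apply_parameter(perturbed, "rt_exo_device_cost_multiplier", mult)
            if substitution is not None:
                perturbed = perturbed.with_(
                    future=apply_substitution(
                        model.current, substitution, model.new_strategy
                    )
                )
            draws[i] = perturbed.evaluate().net_difference
        except (InvalidInputError, InvalidSubstitutionError):
            n_rejected += 1
            if n_rejected > max_rejections:
                raise ModelError(
                    f"PSA rejected {n_rejected} draws; distributions are misspecified"
                ) from None
            continue
        i += 1
    return PSAResult.from_draws(draws, n_rejected=n_rejected)
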