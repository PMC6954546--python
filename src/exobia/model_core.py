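"""Per-strategy cost model for locomotor training in SCI rehabilitation.

A locomotor-training *strategy* (body-weight supported treadmill training,
stationary robotic gait orthosis, overground training, overground robotic
exoskeleton, ...) carries four annual cost components at a given facility:

* **device** — straight-line amortization of the purchase price over the
  device lifespan, allocated to the sessions the device actually serves;
* **maintenance** — the maintenance contract, likewise amortized and
  allocated per session;
* **training** — clinician device-training time, costed at the physical
  therapist wage and amortized over the device lifespan;
* **personnel** — staff time per one-hour session, from the facility wage
  table.

All currency is 2017 USD; the model horizon is one year with no
discounting. Device costs are spread over the facility's device capacity
scaled by an *adoption rate*: the fraction of available device time
clinicians actually use (an idle device still depreciates, but the cost is
attributed only to billable sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "ModelError",
    "InvalidInputError",
    "ConfigurationError",
    "ValidationError",
    "PersonnelRole",
    "Strategy",
    "Facility",
    "CostBreakdown",
    "annual_equivalent_device_cost",
    "per_session_device_cost",
    "per_session_personnel_cost",
    "per_session_total_cost",
    "annualized_training_cost",
    "strategy_annual_cost",
    "PT_ROLE",
    "DEFAULT_CAPACITY_SESSIONS",
    "DEFAULT_ADOPTION_RATE",
]

#: Role whose wage prices clinician training time.
PT_ROLE = "physical_therapist"

#: Default device full-utilization capacity: 8 one-hour session slots/day
#: over 250 operating days/year.
DEFAULT_CAPACITY_SESSIONS = 2000

#: Default clinician adoption rate: the device sits idle half the time.
DEFAULT_ADOPTION_RATE = 0.5

#: Currency rounding unit (whole dollars) used for report output and for
#: component-sum invariants.
CURRENCY_UNIT = 1.0


class ModelError(ValueError):
    """Base class for all model errors."""


class InvalidInputError(ModelError):
    """An operation received an argument outside its valid domain."""


class ConfigurationError(ModelError):
    """Inconsistent configuration, e.g. a personnel role with no wage."""


class ValidationError(ModelError):
    """A domain object violates one of its invariants."""


@dataclass(frozen=True)
class PersonnelRole:
    """One staff role attending a training session.

    ``hourly_wage`` is normally resolved from the facility wage table at
    costing time; setting it here overrides the facility value (used for
    ad-hoc rosters in tests and one-off scenarios).
    """

    role_name: str
    count_per_session: int = 1
    hourly_wage: float | None = None

    def __post_init__(self) -> None:
        if not self.role_name:
            raise ValidationError("personnel role needs a non-empty role_name")
        if self.count_per_session < 0:
            raise ValidationError(
                f"role {self.role_name!r}: count_per_session must be >= 0, "
                f"got {self.count_per_session}"
            )
        if self.hourly_wage is not None and self.hourly_wage <= 0:
            raise ValidationError(
                f"role {self.role_name!r}: hourly_wage must be > 0, got {self.hourly_wage}"
            )


@dataclass(frozen=True)
class Strategy:
    """A locomotor-training modality with its device economics and roster.

    Parameters
    ----------
    device_cost
        Purchase price of the device (0 for device-free delivery).
    maintenance_annual, maintenance_contract_years
        Maintenance contract as an annual charge over a contract length.
        The contract length may differ from the lifespan (e.g. a 5-year
        contract on a 20-year device); the total contract cost is spread
        uniformly over the lifespan.
    lifespan_years
        Useful device life; the amortization horizon for the purchase,
        the maintenance contract, and clinician training.
    personnel
        Staff roster per session (roles and head counts).
    training_hours_per_clinician, trainees_per_site
        One-off device training, costed at the PT wage and amortized over
        the lifespan. Two clinicians trained per site by default.
    session_duration_hours
        One hour including set-up time, by default.
    device_free
        Marks a strategy with no device at all; its device and
        maintenance components are identically zero.
    """

    name: str
    device_cost: float = 0.0
    maintenance_annual: float = 0.0
    maintenance_contract_years: float = 0.0
    lifespan_years: float = 1.0
    personnel: tuple[PersonnelRole, ...] = ()
    training_hours_per_clinician: float = 0.0
    trainees_per_site: int = 2
    session_duration_hours: float = 1.0
    device_free: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "personnel", tuple(self.personnel))
        if not self.name:
            raise ValidationError("strategy needs a non-empty name")
        if self.lifespan_years <= 0:
            raise ValidationError(
                f"strategy {self.name!r}: lifespan_years must be > 0, got {self.lifespan_years}"
            )
        for fld in ("device_cost", "maintenance_annual", "maintenance_contract_years",
                    "training_hours_per_clinician"):
            if getattr(self, fld) < 0:
                raise ValidationError(
                    f"strategy {self.name!r}: {fld} must be >= 0, got {getattr(self, fld)}"
                )
        if self.trainees_per_site < 0:
            raise ValidationError(
                f"strategy {self.name!r}: trainees_per_site must be >= 0"
            )
        if self.session_duration_hours <= 0:
            raise ValidationError(
                f"strategy {self.name!r}: session_duration_hours must be > 0"
            )


def _frozen_map(m: Mapping) -> Mapping:
    return MappingProxyType(dict(m))


@dataclass(frozen=True)
class Facility:
    """A rehabilitation hospital offering locomotor training.

    ``structure`` is either ``LTCH`` (Long Term Acute Care Hospital) or
    ``IRF`` (Inpatient Rehabilitation Facility). ``adoption_rate`` applies
    to every device-based strategy unless overridden per strategy in
    ``adoption_overrides``. ``strategy_overrides`` carries facility-specific
    strategy variants (e.g. a different staffing roster for one modality).
    ``annual_sessions`` is an optional canonical annual session total: some
    source tables print a total that differs slightly from users ×
    sessions/user, and the printed total — which the market-share counts
    are keyed to — then takes precedence.
    """

    label: str
    structure: str
    users_per_year: int
    sessions_per_user: int
    wage_table: Mapping[str, float]
    capacity_sessions_per_year: float = DEFAULT_CAPACITY_SESSIONS
    adoption_rate: float = DEFAULT_ADOPTION_RATE
    adoption_overrides: Mapping[str, float] = field(default_factory=dict)
    strategy_overrides: Mapping[str, Strategy] = field(default_factory=dict)
    annual_sessions: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wage_table", _frozen_map(self.wage_table))
        object.__setattr__(self, "adoption_overrides", _frozen_map(self.adoption_overrides))
        object.__setattr__(self, "strategy_overrides", _frozen_map(self.strategy_overrides))
        if self.structure not in ("LTCH", "IRF"):
            raise ValidationError(
                f"facility {self.label!r}: structure must be 'LTCH' or 'IRF', "
                f"got {self.structure!r}"
            )
        if self.users_per_year < 0:
            raise ValidationError(f"facility {self.label!r}: users_per_year must be >= 0")
        if self.sessions_per_user < 0:
            raise ValidationError(f"facility {self.label!r}: sessions_per_user must be >= 0")
        for role, wage in self.wage_table.items():
            if wage <= 0:
                raise ValidationError(
                    f"facility {self.label!r}: wage for role {role!r} must be > 0, got {wage}"
                )
        if self.capacity_sessions_per_year <= 0:
            raise ValidationError(
                f"facility {self.label!r}: capacity_sessions_per_year must be > 0"
            )
        for name, rate in [("", self.adoption_rate), *self.adoption_overrides.items()]:
            if not (0 < rate <= 1):
                which = f" for strategy {name!r}" if name else ""
                raise ValidationError(
                    f"facility {self.label!r}: adoption rate{which} must be in (0, 1], got {rate}"
                )
        if self.annual_sessions is not None and self.annual_sessions < 0:
            raise ValidationError(
                f"facility {self.label!r}: annual_sessions must be >= 0"
            )

    def adoption_for(self, strategy_name: str) -> float:
        return self.adoption_overrides.get(strategy_name, self.adoption_rate)

    def wage_for(self, role_name: str) -> float:
        try:
            return self.wage_table[role_name]
        except KeyError:
            raise ConfigurationError(
                f"facility {self.label!r} has no wage for role {role_name!r}"
            ) from None

    def resolve_strategies(self, strategies: Mapping[str, Strategy]) -> dict[str, Strategy]:
        """Apply this facility's strategy overrides to a base strategy set."""
        merged = dict(strategies)
        merged.update(self.strategy_overrides)
        return merged


@dataclass(frozen=True)
class CostBreakdown:
    """Annual cost of one strategy at one facility, by component (USD/yr)."""

    strategy_name: str
    n_sessions: int
    device_component: float
    maintenance_component: float
    training_component: float
    personnel_component: float
    total: float

    def __post_init__(self) -> None:
        parts = (self.device_component, self.maintenance_component,
                 self.training_component, self.personnel_component)
        if any(p < 0 for p in parts):
            raise ValidationError(
                f"{self.strategy_name!r}: cost components must be nonnegative, got {parts}"
            )
        if abs(self.total - sum(parts)) > CURRENCY_UNIT:
            raise ValidationError(
                f"{self.strategy_name!r}: total {self.total} does not match "
                f"component sum {sum(parts)}"
            )


def annual_equivalent_device_cost(strategy: Strategy) -> float:
    """Equivalent annual cost of owning one device, USD/year.

    Straight-line amortization: the purchase price plus the total
    maintenance-contract cost, spread uniformly over the lifespan.
    """
    if strategy.lifespan_years <= 0:
        raise InvalidInputError(
            f"strategy {strategy.name!r}: lifespan must be positive"
        )
    if strategy.device_free:
        return 0.0
    contract_total = strategy.maintenance_annual * strategy.maintenance_contract_years
    return (strategy.device_cost + contract_total) / strategy.lifespan_years


def per_session_device_cost(strategy: Strategy, facility: Facility) -> float:
    """Device (incl. maintenance) cost allocated to one billable session.

    The annual equivalent cost is divided over the sessions the device
    actually serves: capacity × adoption rate. A lower adoption rate
    leaves the device idle more, so each billable session carries more of
    the fixed cost.
    """
    if strategy.device_free:
        return 0.0
    adoption = facility.adoption_for(strategy.name)
    if facility.capacity_sessions_per_year <= 0:
        raise InvalidInputError(
            f"facility {facility.label!r}: capacity must be positive"
        )
    if not (0 < adoption <= 1):
        raise InvalidInputError(
            f"facility {facility.label!r}: adoption rate for {strategy.name!r} "
            f"must be in (0, 1], got {adoption}"
        )
    return annual_equivalent_device_cost(strategy) / (
        facility.capacity_sessions_per_year * adoption
    )


def per_session_personnel_cost(strategy: Strategy, facility: Facility) -> float:
    """Staff cost of one session: Σ heads × wage × session duration."""
    cost = 0.0
    for role in strategy.personnel:
        wage = role.hourly_wage if role.hourly_wage is not None else facility.wage_for(role.role_name)
        cost += role.count_per_session * wage * strategy.session_duration_hours
    return cost


def per_session_total_cost(strategy: Strategy, facility: Facility) -> float:
    """Variable cost of one session: personnel plus allocated device cost.

    Excludes the (fixed, annual) training component; used for ranking
    strategies by marginal cost in substitution policies.
    """
    return per_session_personnel_cost(strategy, facility) + per_session_device_cost(
        strategy, facility
    )


def annualized_training_cost(strategy: Strategy, facility: Facility) -> float:
    """Clinician device-training cost, USD/year.

    Trainee time is costed at the facility's physical therapist wage and
    amortized over the device lifespan (training is device-specific).
    """
    hours = strategy.trainees_per_site * strategy.training_hours_per_clinician
    if hours == 0:
        return 0.0
    return hours * facility.wage_for(PT_ROLE) / strategy.lifespan_years


def strategy_annual_cost(
    strategy: Strategy, facility: Facility, n_sessions: int
) -> CostBreakdown:
    """Annual cost breakdown of delivering ``n_sessions`` with a strategy.

    Personnel and device costs scale linearly with session volume; the
    training component is a fixed annual charge incurred whenever the
    strategy is offered at all (``n_sessions > 0``).
    """
    if n_sessions < 0:
        raise InvalidInputError(
            f"strategy {strategy.name!r}: n_sessions must be >= 0, got {n_sessions}"
        )
    personnel = n_sessions * per_session_personnel_cost(strategy, facility)
    aec = annual_equivalent_device_cost(strategy)
    session_device_total = n_sessions * per_session_device_cost(strategy, facility)
    if aec > 0:
        purchase_fraction = (strategy.device_cost / strategy.lifespan_years) / aec
    else:
        purchase_fraction = 0.0
    device = session_device_total * purchase_fraction
    maintenance = session_device_total * (1.0 - purchase_fraction)
    training = annualized_training_cost(strategy, facility) if n_sessions > 0 else 0.0
    total = device + maintenance + training + personnel
    return CostBreakdown(
        strategy_name=strategy.name,
        n_sessions=n_sessions,
        device_component=device,
        maintenance_component=maintenance,
        training_component=training,
        personnel_component=personnel,
        total=total,
    )
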