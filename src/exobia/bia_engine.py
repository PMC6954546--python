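"""Session-volume arithmetic, market-share substitution, and net budget impact.

The budget impact of introducing a new locomotor-training strategy is the
difference in total annual locomotor-training cost between the "world
with" (future market shares) and the "world without" (current market
shares): ``net_difference = future_total - current_total``. Negative
values are savings. Session volumes are conserved between the two worlds
— the new strategy substitutes for existing ones, it does not add demand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .model_core import (
    ConfigurationError,
    CostBreakdown,
    Facility,
    InvalidInputError,
    Strategy,
    ValidationError,
    strategy_annual_cost,
)

__all__ = [
    "SHARE_SUM_TOL",
    "RT_EXO",
    "InvalidSubstitutionError",
    "MarketShareMix",
    "BudgetImpactResult",
    "BiaModel",
    "round_half_up",
    "largest_remainder",
    "sessions_per_year",
    "allocate_sessions",
    "apply_substitution",
    "budget_impact",
]

#: Tolerance on the sum of market shares.
SHARE_SUM_TOL = 0.005

#: Canonical name of the overground robotic exoskeleton strategy.
RT_EXO = "RT_exo"


class InvalidSubstitutionError(ValidationError):
    """A substitution vector would drive a strategy's sessions negative
    or does not balance the new strategy's session count."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (half-up)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def largest_remainder(amount: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``amount`` integer units proportionally to ``weights``.

    Hamilton's method: floor the exact quotas, then hand the remaining
    units to the largest fractional remainders (ties broken by key order,
    which is deterministic for a given mapping). The result sums to
    ``amount`` exactly.
    """
    if amount < 0:
        raise InvalidInputError(f"cannot apportion a negative amount ({amount})")
    total_w = float(sum(weights.values()))
    if amount and total_w <= 0:
        raise InvalidInputError("cannot apportion a positive amount over zero weights")
    if not amount:
        return {k: 0 for k in weights}
    quotas = {k: amount * w / total_w for k, w in weights.items()}
    out = {k: int(q) for k, q in quotas.items()}
    short = amount - sum(out.values())
    by_frac = sorted(weights, key=lambda k: quotas[k] - out[k], reverse=True)
    for k in by_frac[:short]:
        out[k] += 1
    return out


@dataclass(frozen=True)
class MarketShareMix:
    """Per-strategy share of a facility's annual locomotor sessions.

    ``session_counts``, when given, are canonical: printed/observed
    session counts take precedence over the (rounded) percentage shares.
    Shares must lie on the simplex within ``SHARE_SUM_TOL``.
    """

    shares: Mapping[str, float]
    session_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        shares = dict(self.shares)
        object.__setattr__(self, "shares", shares)
        if not shares:
            raise ValidationError("market-share mix must name at least one strategy")
        for name, s in shares.items():
            if s < 0:
                raise ValidationError(f"share for {name!r} must be >= 0, got {s}")
        total = sum(shares.values())
        if abs(total - 1.0) > SHARE_SUM_TOL:
            raise ValidationError(
                f"market shares must sum to 1 within {SHARE_SUM_TOL}, got {total:.4f}"
            )
        if self.session_counts is not None:
            counts = dict(self.session_counts)
            object.__setattr__(self, "session_counts", counts)
            for name, c in counts.items():
                if c < 0 or c != int(c):
                    raise ValidationError(
                        f"session count for {name!r} must be a nonnegative integer, got {c}"
                    )
            if set(counts) != set(shares):
                raise ValidationError(
                    "session_counts and shares must cover the same strategies"
                )

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MarketShareMix":
        """Build a mix from session counts; shares are derived exactly."""
        total = sum(counts.values())
        if total <= 0:
            raise ValidationError("cannot derive shares from all-zero session counts")
        shares = {k: c / total for k, c in counts.items()}
        return cls(shares=shares, session_counts={k: int(c) for k, c in counts.items()})

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(self.shares)

    def check_counts_total(self, total_sessions: int, context: str = "") -> None:
        """Warn when canonical counts disagree with the facility's annual
        total by more than rounding slack (one session per strategy).

        Printed source tables are occasionally internally inconsistent;
        such mixes are usable but flagged.
        """
        if self.session_counts is None:
            return
        count_sum = sum(self.session_counts.values())
        slack = len(self.session_counts)
        if abs(count_sum - total_sessions) > slack:
            warnings.warn(
                f"{context or 'mix'}: session counts sum to {count_sum}, "
                f"expected {total_sessions} ± {slack}; counts kept as given",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BudgetImpactResult:
    """Current-world vs future-world annual cost at one facility (USD/yr).

    ``net_difference = future_total - current_total``; negative = savings.
    """

    facility_label: str
    current_total: float
    future_total: float
    net_difference: float
    current_breakdowns: Mapping[str, CostBreakdown]
    future_breakdowns: Mapping[str, CostBreakdown]

    def __post_init__(self) -> None:
        if self.net_difference != self.future_total - self.current_total:
            raise ValidationError("net_difference must equal future_total - current_total")
        for total, breakdowns, world in (
            (self.current_total, self.current_breakdowns, "current"),
            (self.future_total, self.future_breakdowns, "future"),
        ):
            if abs(total - sum(b.total for b in breakdowns.values())) > 1.0:
                raise ValidationError(f"{world} total does not match its breakdowns")

    @property
    def is_saving(self) -> bool:
        return self.net_difference < 0


def sessions_per_year(facility: Facility) -> int:
    """Annual locomotor-training sessions: eligible users × sessions/user.

    A canonical ``annual_sessions`` on the facility (a printed total the
    market-share counts are keyed to) takes precedence over the product.
    """
    if facility.annual_sessions is not None:
        return facility.annual_sessions
    return facility.users_per_year * facility.sessions_per_user


def allocate_sessions(total: int, mix: MarketShareMix) -> dict[str, int]:
    """Split an annual session total across strategies.

    Canonical session counts, when present, are returned unchanged;
    otherwise each strategy gets ``round_half_up(total × share)``.
    """
    if total < 0:
        raise InvalidInputError(f"total sessions must be >= 0, got {total}")
    if mix.session_counts is not None:
        return dict(mix.session_counts)
    return {name: round_half_up(total * share) for name, share in mix.shares.items()}


def apply_substitution(
    current: MarketShareMix,
    substitution: Mapping[str, int],
    new_strategy: str = RT_EXO,
    new_sessions: int | None = None,
) -> MarketShareMix:
    """Move sessions from donor strategies to a (new) recipient strategy.

    ``substitution`` maps each donor to the number of sessions it gives
    up. The recipient receives the donated total, or ``new_sessions``
    when an explicit (e.g. printed) count is supplied — allowed to differ
    from the donated sum by at most one session per strategy, absorbing
    rounding in published tables. Total sessions are conserved to within
    that slack.
    """
    if current.session_counts is None:
        raise ValidationError(
            "apply_substitution needs canonical session counts on the current mix; "
            "allocate sessions first"
        )
    counts = dict(current.session_counts)
    donated = 0
    for donor, d in substitution.items():
        if d < 0:
            raise InvalidSubstitutionError(f"negative donation from {donor!r}: {d}")
        if donor not in counts:
            raise ConfigurationError(f"donor strategy {donor!r} not in current mix")
        if d > counts[donor]:
            raise InvalidSubstitutionError(
                f"strategy {donor!r} donates {d} sessions but only has {counts[donor]}"
            )
        counts[donor] -= d
        donated += d
    received = donated if new_sessions is None else int(new_sessions)
    slack = len(counts) + 1
    if new_sessions is not None and abs(received - donated) > slack:
        raise InvalidSubstitutionError(
            f"{new_strategy!r} receives {received} sessions but donors gave {donated} "
            f"(allowed rounding slack ±{slack})"
        )
    counts[new_strategy] = counts.get(new_strategy, 0) + received
    return MarketShareMix.from_counts(counts)


def budget_impact(
    facility: Facility,
    strategies: Mapping[str, Strategy],
    current: MarketShareMix,
    future: MarketShareMix,
) -> BudgetImpactResult:
    """Net budget impact of moving a facility from ``current`` to ``future``.

    Both worlds are costed with :func:`strategy_annual_cost` over the
    facility's annual session volume; the net difference (future −
    current) is the budget impact of the substitution.
    """
    total = sessions_per_year(facility)
    resolved = facility.resolve_strategies(strategies)
    result_worlds: list[tuple[float, dict[str, CostBreakdown]]] = []
    for world_name, mix in (("current", current), ("future", future)):
        mix.check_counts_total(total, context=f"facility {facility.label} {world_name} mix")
        counts = allocate_sessions(total, mix)
        breakdowns: dict[str, CostBreakdown] = {}
        for name, n in counts.items():
            if name not in resolved:
                raise ConfigurationError(
                    f"facility {facility.label!r}: strategy {name!r} appears in the "
                    f"{world_name} mix but is not defined"
                )
            breakdowns[name] = strategy_annual_cost(resolved[name], facility, n)
        result_worlds.append((sum(b.total for b in breakdowns.values()), breakdowns))
    (current_total, current_bd), (future_total, future_bd) = result_worlds
    return BudgetImpactResult(
        facility_label=facility.label,
        current_total=current_total,
        future_total=future_total,
        net_difference=future_total - current_total,
        current_breakdowns=current_bd,
        future_breakdowns=future_bd,
    )


@dataclass(frozen=True)
class BiaModel:
    """A fully specified base case: facility, strategy set, both worlds.

    Bundles everything :func:`budget_impact` needs so sensitivity
    analyses can perturb one input at a time via :meth:`with_`.
    """

    facility: Facility
    strategies: Mapping[str, Strategy]
    current: MarketShareMix
    future: MarketShareMix
    new_strategy: str = RT_EXO

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", dict(self.strategies))

    def evaluate(self) -> BudgetImpactResult:
        return budget_impact(self.facility, self.strategies, self.current, self.future)

    def with_(self, **changes) -> "BiaModel":
        return replace(self, **changes)

    def current_counts(self) -> dict[str, int]:
        return allocate_sessions(sessions_per_year(self.facility), self.current)

    def future_counts(self) -> dict[str, int]:
        return allocate_sessions(sessions_per_year(self.facility), self.future)

    def donation_vector(self) -> dict[str, int]:
        """Sessions each donor strategy gives up between the two worlds."""
        cur, fut = self.current_counts(), self.future_counts()
        return {
            name: cur[name] - fut.get(name, 0)
            for name in cur
            if name != self.new_strategy and cur[name] - fut.get(name, 0) > 0
        }

    def new_strategy_sessions(self) -> int:
        return self.future_counts().get(self.new_strategy, 0)
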