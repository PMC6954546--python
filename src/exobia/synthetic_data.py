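"""Generator of random-but-valid facilities and market-share mixes.

Emulates the structure of the study inputs — positive session volumes,
market shares on a simplex, wage vectors in plausible US therapist
ranges, and a substitution vector moving a target share of sessions from
conventional strategies to the overground exoskeleton — so every model
stage can be exercised without any real-world input. Shares are
generated in session-count space (Dirichlet weights apportioned to
integer counts), so current and future worlds conserve sessions exactly
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bia_engine import (
    BiaModel,
    MarketShareMix,
    apply_substitution,
    largest_remainder,
    round_half_up,
)
from .fixtures import base_strategies
from .model_core import Facility, InvalidInputError, Strategy, ValidationError

__all__ = ["SynthSpec", "SynthBundle", "generate"]

#: Conventional (donor) strategies offered in every generated facility.
CONVENTIONAL = ("BWSTT", "stationary_robotic", "OGT_low")

_DEFAULT_WAGE_RANGES = {
    "physical_therapist": (35.0, 55.0),
    "exercise_specialist": (18.0, 30.0),
    "aide": (12.0, 20.0),
}


@dataclass(frozen=True)
class SynthSpec:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the scale of the four study facilities: 80–260
    eligible users/year, 12–26 sessions per user, therapist wages in
    2017-plausible hourly ranges, and an exoskeleton target share of 10%
    of annual sessions.
    """

    seed: int
    n_facilities: int = 4
    users_range: tuple[int, int] = (80, 260)
    sessions_per_user_range: tuple[int, int] = (12, 26)
    wage_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WAGE_RANGES)
    )
    share_concentration: float = 5.0
    rt_exo_target_share: float = 0.10

    def __post_init__(self) -> None:
        if self.n_facilities < 1:
            raise ValidationError(f"n_facilities must be >= 1, got {self.n_facilities}")
        for name, (lo, hi) in (
            ("users_range", self.users_range),
            ("sessions_per_user_range", self.sessions_per_user_range),
        ):
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be a nonempty positive interval")
        for role, (lo, hi) in dict(self.wage_ranges).items():
            if not (0 < lo <= hi):
                raise ValidationError(
                    f"wage range for {role!r} must be a nonempty positive interval"
                )
        if self.share_concentration <= 0:
            raise ValidationError("share_concentration must be > 0")
        if not (0 < self.rt_exo_target_share < 1):
            raise InvalidInputError(
                f"rt_exo_target_share must be in (0, 1), got {self.rt_exo_target_share}"
            )


@dataclass(frozen=True)
class SynthBundle:
    """A generated study: strategies, facilities, mixes, donor vectors."""

    strategies: Mapping[str, Strategy]
    facilities: Mapping[str, Facility]
    mixes: Mapping[tuple[str, str], MarketShareMix]
    substitutions: Mapping[str, Mapping[str, int]]

    def model(self, label: str) -> BiaModel:
        return BiaModel(
            facility=self.facilities[label],
            strategies=self.strategies,
            current=self.mixes[(label, "current")],
            future=self.mixes[(label, "future")],
        )

    def models(self) -> dict[str, BiaModel]:
        return {label: self.model(label) for label in self.facilities}


def _label(i: int) -> str:
    # A, B, ..., Z, S26, S27, ...
    return chr(ord("A") + i) if i < 26 else f"S{i}"


def generate(spec: SynthSpec) -> SynthBundle:
    """Generate a bundle of valid synthetic facilities.

    Deterministic for a given spec: the same seed yields the identical
    bundle. Every generated object satisfies its type invariants by
    construction, and future mixes conserve the current world's total
    sessions exactly.
    """
    rng = np.random.default_rng(spec.seed)
    strategies = base_strategies()
    facilities: dict[str, Facility] = {}
    mixes: dict[tuple[str, str], MarketShareMix] = {}
    substitutions: dict[str, dict[str, int]] = {}
    for i in range(spec.n_facilities):
        label = _label(i)
        users = int(rng.integers(spec.users_range[0], spec.users_range[1] + 1))
        sessions_per_user = int(
            rng.integers(spec.sessions_per_user_range[0], spec.sessions_per_user_range[1] + 1)
        )
        wages = {
            role: float(np.round(rng.uniform(lo, hi), 2))
            for role, (lo, hi) in sorted(dict(spec.wage_ranges).items())
        }
        facility = Facility(
            label=label,
            structure=("LTCH", "IRF")[int(rng.integers(0, 2))],
            users_per_year=users,
            sessions_per_user=sessions_per_user,
            wage_table=wages,
        )
        total = users * sessions_per_user
        weights = rng.dirichlet(np.full(len(CONVENTIONAL), spec.share_concentration))
        current_counts = largest_remainder(total, dict(zip(CONVENTIONAL, weights.tolist())))
        # degenerate Dirichlet draws can zero a strategy; keep it offered
        for name in CONVENTIONAL:
            current_counts.setdefault(name, 0)
        current = MarketShareMix.from_counts(current_counts)
        rt_sessions = round_half_up(spec.rt_exo_target_share * total)
        donors = {n: c for n, c in current_counts.items() if c > 0}
        donation = largest_remainder(rt_sessions, donors)
        future = apply_substitution(current, donation, "RT_exo")
        facilities[label] = facility
        mixes[(label, "current")] = current
        mixes[(label, "future")] = future
        substitutions[label] = donation
    return SynthBundle(
        strategies=strategies,
        facilities=facilities,
        mixes=mixes,
        substitutions=substitutions,
    )
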