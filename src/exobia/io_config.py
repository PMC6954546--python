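"""Readers and writers for model configuration and result reports.

Configuration is declarative YAML (or JSON): a ``strategies`` list, a
``facilities`` list, and a ``mixes`` list keyed by facility label and
world (``current`` / ``future``). All domain invariants are enforced at
load time, so a loaded configuration is a valid model by construction.

Reports are CSV with a stable column order and currency rounded half-up
to whole dollars; identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .bia_engine import BudgetImpactResult, MarketShareMix, round_half_up
from .model_core import (
    ConfigurationError,
    Facility,
    PersonnelRole,
    Strategy,
    ValidationError,
)

__all__ = [
    "SCHEMA_VERSION",
    "REPORT_COLUMNS",
    "load_config",
    "write_config",
    "write_report",
    "config_to_dict",
]

SCHEMA_VERSION = 1

REPORT_COLUMNS = [
    "facility",
    "world",
    "strategy",
    "n_sessions",
    "device",
    "maintenance",
    "training",
    "personnel",
    "total",
]


def _parse_personnel(raw: Iterable[Mapping], where: str) -> tuple[PersonnelRole, ...]:
    roles = []
    for entry in raw:
        if "role" not in entry:
            raise ConfigurationError(f"{where}: personnel entry missing 'role': {entry!r}")
        roles.append(
            PersonnelRole(
                role_name=str(entry["role"]),
                count_per_session=int(entry.get("count", 1)),
                hourly_wage=entry.get("hourly_wage"),
            )
        )
    return tuple(roles)


_STRATEGY_FIELDS = {
    "device_cost": float,
    "maintenance_annual": float,
    "maintenance_contract_years": float,
    "lifespan_years": float,
    "training_hours_per_clinician": float,
    "trainees_per_site": int,
    "session_duration_hours": float,
    "device_free": bool,
}


def _parse_strategy(raw: Mapping, where: str, base: Strategy | None = None) -> Strategy:
    name = raw.get("name") or (base.name if base else None)
    if not name:
        raise ConfigurationError(f"{where}: strategy entry missing 'name'")
    kwargs = {}
    for fld, cast in _STRATEGY_FIELDS.items():
        if fld in raw:
            kwargs[fld] = cast(raw[fld])
        elif base is not None:
            kwargs[fld] = getattr(base, fld)
    if "personnel" in raw:
        kwargs["personnel"] = _parse_personnel(raw["personnel"], where)
    elif base is not None:
        kwargs["personnel"] = base.personnel
    try:
        return Strategy(name=str(name), **kwargs)
    except ValidationError as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc


def _parse_facility(raw: Mapping, strategies: Mapping[str, Strategy]) -> Facility:
    label = raw.get("label")
    if not label:
        raise ConfigurationError("facility entry missing 'label'")
    where = f"facility {label!r}"
    for required in ("structure", "users_per_year", "sessions_per_user", "wage_table"):
        if required not in raw:
            raise ConfigurationError(f"{where}: missing required field {required!r}")
    overrides = {}
    for name, patch in (raw.get("strategy_overrides") or {}).items():
        if name not in strategies:
            raise ConfigurationError(
                f"{where}: strategy_overrides refers to unknown strategy {name!r}"
            )
        overrides[name] = _parse_strategy(
            dict(patch, name=name), f"{where} override {name!r}", base=strategies[name]
        )
    try:
        return Facility(
            label=str(label),
            structure=str(raw["structure"]),
            users_per_year=int(raw["users_per_year"]),
            sessions_per_user=int(raw["sessions_per_user"]),
            wage_table={str(k): float(v) for k, v in raw["wage_table"].items()},
            capacity_sessions_per_year=float(
                raw.get("capacity_sessions_per_year", Facility.capacity_sessions_per_year)
            ),
            adoption_rate=float(raw.get("adoption_rate", Facility.adoption_rate)),
            adoption_overrides={
                str(k): float(v) for k, v in (raw.get("adoption_overrides") or {}).items()
            },
            strategy_overrides=overrides,
            annual_sessions=(
                int(raw["annual_sessions"]) if raw.get("annual_sessions") is not None else None
            ),
        )
    except ValidationError as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc


def _parse_mix(raw: Mapping) -> tuple[tuple[str, str], MarketShareMix]:
    for required in ("facility", "world", "shares"):
        if required not in raw:
            raise ConfigurationError(f"mix entry missing required field {required!r}: {raw!r}")
    label, world = str(raw["facility"]), str(raw["world"])
    if world not in ("current", "future"):
        raise ConfigurationError(
            f"mix for facility {label!r}: world must be 'current' or 'future', got {world!r}"
        )
    counts = raw.get("session_counts")
    try:
        mix = MarketShareMix(
            shares={str(k): float(v) for k, v in raw["shares"].items()},
            session_counts=None if counts is None
            else {str(k): int(v) for k, v in counts.items()},
        )
    except ValidationError as exc:
        raise ConfigurationError(f"mix for facility {label!r} ({world}): {exc}") from exc
    return (label, world), mix


def load_config(
    path: str | Path,
) -> tuple[dict[str, Strategy], dict[str, Facility], dict[tuple[str, str], MarketShareMix]]:
    """Load and validate a model configuration file.

    Returns ``(strategies, facilities, mixes)``: strategies keyed by
    name, facilities by label, mixes by ``(facility_label, world)``.
    Any invariant violation raises :class:`ConfigurationError` naming
    the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"{path}: unsupported schema_version {version} (expected {SCHEMA_VERSION})"
        )
    strat_entries = raw.get("strategies") or []
    if not strat_entries:
        raise ConfigurationError(f"{path}: 'strategies' list is empty or missing")
    strategies: dict[str, Strategy] = {}
    for entry in strat_entries:
        s = _parse_strategy(entry, f"{path}: strategies")
        if s.name in strategies:
            raise ConfigurationError(f"{path}: duplicate strategy {s.name!r}")
        strategies[s.name] = s
    facilities: dict[str, Facility] = {}
    for entry in raw.get("facilities") or []:
        f = _parse_facility(entry, strategies)
        if f.label in facilities:
            raise ConfigurationError(f"{path}: duplicate facility {f.label!r}")
        facilities[f.label] = f
    mixes: dict[tuple[str, str], MarketShareMix] = {}
    for entry in raw.get("mixes") or []:
        key, mix = _parse_mix(entry)
        if key[0] not in facilities:
            raise ConfigurationError(
                f"{path}: mix refers to unknown facility {key[0]!r}"
            )
        for name in mix.shares:
            if name not in strategies:
                raise ConfigurationError(
                    f"{path}: mix for facility {key[0]!r} refers to unknown "
                    f"strategy {name!r}"
                )
        mixes[key] = mix
    return strategies, facilities, mixes


def config_to_dict(
    strategies: Mapping[str, Strategy],
    facilities: Mapping[str, Facility],
    mixes: Mapping[tuple[str, str], MarketShareMix],
) -> dict:
    """Serialize domain objects to a plain config mapping (inverse of load)."""

    def _strategy(s: Strategy) -> dict:
        return {
            "name": s.name,
            "device_cost": s.device_cost,
            "maintenance_annual": s.maintenance_annual,
            "maintenance_contract_years": s.maintenance_contract_years,
            "lifespan_years": s.lifespan_years,
            "personnel": [
                {"role": r.role_name, "count": r.count_per_session,
                 **({"hourly_wage": r.hourly_wage} if r.hourly_wage is not None else {})}
                for r in s.personnel
            ],
            "training_hours_per_clinician": s.training_hours_per_clinician,
            "trainees_per_site": s.trainees_per_site,
            "session_duration_hours": s.session_duration_hours,
            "device_free": s.device_free,
        }

    def _facility(f: Facility) -> dict:
        out = {
            "label": f.label,
            "structure": f.structure,
            "users_per_year": f.users_per_year,
            "sessions_per_user": f.sessions_per_user,
            "wage_table": dict(f.wage_table),
            "capacity_sessions_per_year": f.capacity_sessions_per_year,
            "adoption_rate": f.adoption_rate,
        }
        if f.annual_sessions is not None:
            out["annual_sessions"] = f.annual_sessions
        if f.adoption_overrides:
            out["adoption_overrides"] = dict(f.adoption_overrides)
        if f.strategy_overrides:
            out["strategy_overrides"] = {
                name: {k: v for k, v in _strategy(s).items() if k != "name"}
                for name, s in f.strategy_overrides.items()
            }
        return out

    return {
        "schema_version": SCHEMA_VERSION,
        "strategies": [_strategy(s) for s in strategies.values()],
        "facilities": [_facility(f) for f in facilities.values()],
        "mixes": [
            {
                "facility": label,
                "world": world,
                "shares": dict(mix.shares),
                **(
                    {"session_counts": dict(mix.session_counts)}
                    if mix.session_counts is not None
                    else {}
                ),
            }
            for (label, world), mix in mixes.items()
        ],
    }


def write_config(
    strategies: Mapping[str, Strategy],
    facilities: Mapping[str, Facility],
    mixes: Mapping[tuple[str, str], MarketShareMix],
    path: str | Path,
) -> Path:
    """Write a configuration file (YAML, or JSON by extension)."""
    path = Path(path)
    payload = config_to_dict(strategies, facilities, mixes)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def results_frame(results: Iterable[BudgetImpactResult]) -> pd.DataFrame:
    """Flatten budget-impact results into a per-strategy table.

    One row per (facility, world, strategy) plus a TOTAL row per world,
    currency rounded half-up to whole 2017 USD.
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to report")
    rows = []
    for res in results:
        for world, breakdowns, total in (
            ("current", res.current_breakdowns, res.current_total),
            ("future", res.future_breakdowns, res.future_total),
        ):
            for name, b in breakdowns.items():
                rows.append(
                    {
                        "facility": res.facility_label,
                        "world": world,
                        "strategy": name,
                        "n_sessions": b.n_sessions,
                        "device": round_half_up(b.device_component),
                        "maintenance": round_half_up(b.maintenance_component),
                        "training": round_half_up(b.training_component),
                        "personnel": round_half_up(b.personnel_component),
                        "total": round_half_up(b.total),
                    }
                )
            rows.append(
                {
                    "facility": res.facility_label,
                    "world": world,
                    "strategy": "TOTAL",
                    "n_sessions": sum(b.n_sessions for b in breakdowns.values()),
                    "device": round_half_up(sum(b.device_component for b in breakdowns.values())),
                    "maintenance": round_half_up(
                        sum(b.maintenance_component for b in breakdowns.values())
                    ),
                    "training": round_half_up(
                        sum(b.training_component for b in breakdowns.values())
                    ),
                    "personnel": round_half_up(
                        sum(b.personnel_component for b in breakdowns.values())
                    ),
                    "total": round_half_up(total),
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(results: Iterable[BudgetImpactResult], path: str | Path) -> Path:
    """Write the per-strategy cost report as CSV.

    Raises before touching the filesystem if the result set is empty;
    identical inputs yield byte-identical files.
    """
    frame = results_frame(results)  # validates non-emptiness first
    path = Path(path)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path
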