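"""Summary reporting across facilities and run manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .bia_engine import BudgetImpactResult, round_half_up
from .model_core import ValidationError

__all__ = ["SummaryTable", "summarize_all", "RunManifest", "write_manifest"]

SUMMARY_COLUMNS = ["facility", "current_total", "future_total", "net_difference", "direction"]


@dataclass(frozen=True)
class SummaryTable:
    """Four-facility style summary: one row per facility plus extremes."""

    table: pd.DataFrame
    min_net_difference: int
    max_net_difference: int


def summarize_all(results: Iterable[BudgetImpactResult]) -> SummaryTable:
    """Condense budget-impact results into one row per facility.

    Currency is rounded half-up to whole dollars. A negative net
    difference is labelled ``savings`` (the adopting facility spends
    less in the world with the new strategy), a positive one ``cost``.
    """
    results = list(results)
    if not results:
        raise ValidationError("summarize_all needs at least one result")
    rows = []
    for res in results:
        net = round_half_up(res.net_difference)
        rows.append(
            {
                "facility": res.facility_label,
                "current_total": round_half_up(res.current_total),
                "future_total": round_half_up(res.future_total),
                "net_difference": net,
                "direction": "savings" if net < 0 else ("cost" if net > 0 else "neutral"),
            }
        )
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    nets = table["net_difference"]
    return SummaryTable(
        table=table,
        min_net_difference=int(nets.min()),
        max_net_difference=int(nets.max()),
    )


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every CLI output file."""

    command: str
    config_paths: Sequence[str]
    seed: int | None
    package_version: str
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config_paths": list(self.config_paths),
            "seed": self.seed,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
        }


def write_manifest(
    out_path: str | Path,
    command: str,
    config_paths: Sequence[str | Path],
    seed: int | None = None,
    extra: Mapping | None = None,
) -> Path:
    """Write a JSON manifest next to ``out_path`` (as ``<out>.manifest.json``)."""
    out_path = Path(out_path)
    manifest = RunManifest(
        command=command,
        config_paths=[str(p) for p in config_paths],
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    payload = manifest.to_dict()
    if extra:
        payload.update(dict(extra))
    manifest_path = out_path.with_name(out_path.name + ".manifest.json")
    manifest_path.write_text(json.dumps(payload, indent=2) + "\n")
    return manifest_path
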