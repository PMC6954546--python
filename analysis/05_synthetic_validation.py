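#!/usr/bin/env python
"""Validation on synthetic facilities: when does the exoskeleton save?

Generates 1000 random-but-valid facilities, evaluates the budget impact
of a 10% exoskeleton substitution at each, and relates the sign of the
net difference to the facility's mix of personnel-heavy donors.
"""

import warnings
from pathlib import Path

import pandas as pd

from exobia import SynthSpec, generate, per_session_total_cost, sessions_per_year

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 13


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    bundle = generate(SynthSpec(seed=SEED, n_facilities=1000))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, model in bundle.models().items():
            resolved = model.facility.resolve_strategies(model.strategies)
            counts = model.current_counts()
            total = sum(counts.values())
            donor_cost = sum(
                c * per_session_total_cost(resolved[n], model.facility)
                for n, c in counts.items()
            ) / total
            exo_cost = per_session_total_cost(resolved["RT_exo"], model.facility)
            rows.append(
                {
                    "facility": label,
                    "sessions": sessions_per_year(model.facility),
                    "donor_weighted_cost_per_session": round(donor_cost, 2),
                    "exo_cost_per_session": round(exo_cost, 2),
                    "net_difference": round(model.evaluate().net_difference),
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "synthetic_facilities.csv", index=False)
    savings = (frame["net_difference"] < 0).mean()
    cheaper = frame["exo_cost_per_session"] < frame["donor_weighted_cost_per_session"]
    agree = ((frame["net_difference"] < 0) == cheaper).mean()
    print(f"{len(frame)} synthetic facilities: {savings:.1%} show savings.")
    print(
        f"Sign of the net difference agrees with the per-session cost ordering "
        f"(exoskeleton vs session-weighted donor average) in {agree:.1%} of "
        f"facilities — the small residual is the fixed training charge and "
        f"count rounding."
    )
    assert (frame["net_difference"] < 0).any() and (frame["net_difference"] > 0).any()


if __name__ == "__main__":
    main()
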