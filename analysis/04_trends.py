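#!/usr/bin/env python
"""Rate-trend analysis: which reaction dominates, and when trends flip.

Classifies all 12 reaction rates as always-positive / always-negative /
mixed (trend threshold xi = 0.6) and, for the mixed ones, localizes the
expected extracellular potassium count at the first trend change, by both
the first-entry and the transport-reward routes.  Writes per-convention
tables and a trend-annotated DOT rendering of the cycle.
"""

from pathlib import Path

import pandas as pd

from pumpmc import (
    KineticParameters,
    TrendConfig,
    VolumeContext,
    build_network,
    classify_rate_trends,
    explore,
)
from pumpmc.statespace import to_dot

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

for rounding in ("ceiling", "nearest"):
    ctmc = explore(
        build_network(KineticParameters(), VolumeContext(volume=1e-20, rounding=rounding))
    )
    report = classify_rate_trends(ctmc, TrendConfig(xi=0.6))
    rows = []
    for lab, cls in report.classification.items():
        flip = report.flips.get(lab)
        rows.append(
            {
                "reaction": lab,
                "classification": cls,
                "flip_expected_kout": flip.expected_kout if flip and flip.flipped else None,
                "flip_reward_route": (
                    flip.expected_kout_reward_route if flip and flip.flipped else None
                ),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / f"trends_{rounding}.csv", index=False)
    (OUT / f"trends_{rounding}.dot").write_text(
        to_dot(ctmc, decorations=report.decorations())
    )
    print(f"--- {rounding} (KO = {ctmc.network.KO}) ---")
    print(table.to_string(index=False))

print(
    "\nThe early forward steps never dominate (binding of intracellular Na "
    "competes with fast K_i rebinding); the final K release r6 always does. "
    "The middle steps lose dominance as ADP, Na_o and P_i accumulate, which "
    "is why forward progress, and hence depletion, slows over time."
)
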