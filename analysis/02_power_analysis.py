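#!/usr/bin/env python
"""Design-stage power analysis: how many daily censuses are needed to
detect a departure of mean sharing from the neutral level S0 = 3.59
(six animals, six pots), as a function of the effect ratio mean/S0.

Writes results/power_curve.tsv (ratio grid for M = 5 and M = 10).
"""
from pathlib import Path

import numpy as np
import pandas as pd

from denshare.neutral import PowerSpec, power_curve

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

ratios = np.round(np.arange(0.1, 1.91, 0.05), 10)
frames = []
for m in (5, 10):
    df = power_curve(PowerSpec(6, 6, m, alpha=0.05), ratios)
    df["m_days"] = m
    frames.append(df)
out = pd.concat(frames, ignore_index=True)
out.to_csv(OUT / "power_curve.tsv", sep="\t", index=False)

m5 = frames[0].set_index("ratio")
print(out.pivot(index="ratio", columns="m_days", values="power").round(3).to_string())
print(
    f"\nAt M = 5 days: power {m5.loc[0.55, 'power']:.2f} at 55% of neutral sharing "
    f"(anti-social side detectable), {m5.loc[1.35, 'power']:.2f} at 135% "
    f"(the social side needs more days than the published design analysis claimed)."
)
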