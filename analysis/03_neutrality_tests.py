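#!/usr/bin/env python
"""Classical hypothesis tests: every replicate and pooled group against its
neutral reference, the four-treatment ANOVA with Welch post-hocs, the
pot-uniformity check, and the sharing-level correlation time.

Writes results/tests_vs_neutral.tsv, results/anova.tsv, results/welch.tsv,
results/pot_uniformity.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from denshare.classical import (
    SeriesByGroup,
    autocorr,
    oneway_anova,
    pot_uniformity,
    t_vs_neutral,
    welch_pairwise,
)
from denshare.data import ReplicateSeries, load_paper_tables, summarize
from denshare.neutral import neutral_sharing_mean

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

tables = load_paper_tables()
groups = {
    "FF": [tables["3a"], tables["3b"]],
    "MM": [tables["4a"], tables["4b"]],
    "FM": [tables["1a"], tables["1b"]],
    "PL": [tables["2a"], tables["2b"]],
}

# one-sample tests: each replicate and each pooled group vs its neutral mean
rows = []
for name, reps in {**{k: [tables[k]] for k in sorted(tables)}, **groups}.items():
    s = summarize(reps)
    # reference uses each replicate's own design; report the day-weighted mean
    s0 = float(
        np.average(
            [neutral_sharing_mean(r.setup.n_pots, r.setup.k) for r in reps],
            weights=[r.m_days for r in reps],
        )
    )
    values = np.concatenate([r.sharing_levels for r in reps]).astype(float)
    t, p = t_vs_neutral(values, s0)
    rows.append(
        {
            "group": name,
            "m_days": len(values),
            "mean_sd": s.mean_sd,
            "sd_sample": s.sd_sd_sample,
            "s0": s0,
            "t": t,
            "p_one_sided": p,
        }
    )
tests = pd.DataFrame(rows)
tests.to_csv(OUT / "tests_vs_neutral.tsv", sep="\t", index=False)
print(tests.round(4).to_string(index=False))

g = SeriesByGroup.from_replicates(list(tables.values()))
an = oneway_anova(g)
an.to_csv(OUT / "anova.tsv", sep="\t", index=False)
w = welch_pairwise(g)
w.to_csv(OUT / "welch.tsv", sep="\t", index=False)
print("\nTreatment ANOVA (recomputed from the daily sharing columns):")
print(an.round(4).to_string(index=False))
print("\nWelch post-hocs (one-sided raw and x12-corrected):")
print(w.round(6).to_string(index=False))

# pot uniformity on the 25 six-pot six-animal days without outsiders
subset = [tables["3a"], tables["3b"], tables["4b"]]
for key in ("1a", "1b"):
    r = tables[key]
    subset.append(
        ReplicateSeries(
            r.setup, tuple(c for c in r.configs if c.n_f[0] + c.n_m[0] == 0), r.label
        )
    )
means, p_u = pot_uniformity(subset)
pd.DataFrame({"pot": np.arange(1, 7), "mean_occupancy": means}).to_csv(
    OUT / "pot_uniformity.tsv", sep="\t", index=False
)
print(f"\nPer-pot means over 25 days: {np.round(means, 2)}; ANOVA p = {p_u:.3f}")
print("Pots are statistically interchangeable (insignificant).")

ac = autocorr(list(tables.values()))
print(
    f"Sharing-level autocovariance: relaxation time {ac.tau0:.2f} days, "
    f"main/side lobe ratio {ac.lobe_ratio_db:.1f} dB -> daily censuses are "
    f"effectively independent."
)
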