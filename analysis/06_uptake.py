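#!/usr/bin/env python
"""Glycine-uptake analysis: rates, percent of WT, membrane normalization.

Reads the uptake plate and membrane-level table written by
01_simulate_inputs.py, converts to nmol/min/mg rates, expresses each
genotype relative to WT, normalizes by cytomembrane GLYT1 level, and runs
the one-way ANOVA with Dunnett contrasts against WT — before and after
membrane normalization (deficient variants should lose significance after,
i.e. their transport machinery is intact but under-presented).
"""

from pathlib import Path

import pandas as pd

from spinecpg import io, uptake

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs"
OUT = ROOT / "results"

plate = io.read_plate_csv(INPUTS / "uptake_plate.csv")
membrane = io.read_membrane_csv(INPUTS / "membrane_levels.csv")

rates = uptake.plate_rates(plate)
pct = uptake.percent_of_wt(rates)
norm = uptake.membrane_normalized_uptake(pct, membrane)
norm.to_csv(OUT / "uptake_normalized.csv", index=False)

summary = (norm.groupby("genotype")
           .agg(mean_rate=("rate", "mean"),
                pct_of_wt=("percent_of_wt", "mean"),
                membrane_norm_pct=("membrane_normalized_pct", "mean"))
           .round(2))
print(summary.to_string())

for column, label in (("percent_of_wt", "raw percent of WT"),
                      ("membrane_normalized_pct", "membrane-normalized")):
    groups = {g: sub[column].to_numpy() for g, sub in norm.groupby("genotype")}
    res = uptake.compare_to_wt(groups)
    sig = res.contrasts[res.contrasts["p_adjusted"] < 0.05]["genotype"].tolist()
    print(f"{label}: ANOVA F = {res.anova_f:.1f}, p = {res.anova_p:.3g}; "
          f"variants differing from WT (Dunnett, α = 0.05): {sig or 'none'}")
print(f"wrote {OUT / 'uptake_normalized.csv'}")
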