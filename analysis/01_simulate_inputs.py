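#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/: bilateral calcium traces for a
coordinated ("wt") and a discoordinated ("mutant") fish, fish midlines with
metadata, cohort allele-count tables, a four-channel sEMG recording, a
glycine-uptake plate with membrane levels, and a small gene-set GMT.
"""

from pathlib import Path

import numpy as np

from spinecpg import io, synthetic as syn
from spinecpg.enrichment import write_gmt

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# -- bilateral calcium traces: coordinated vs discoordinated fish ----------
# wt-like: reliable left-right switching; mutant-like: switching is nearly
# random and events are sparser/weaker (stronger glycinergic inhibition)
conditions = {
    "wt": syn.CPGSimParams(seed=101, switch_prob=0.9, event_rate=0.25),
    "mutant": syn.CPGSimParams(seed=102, switch_prob=0.5, event_rate=0.12,
                               amplitude_mean=18.0),
}
for label, params in conditions.items():
    traces, truth = syn.simulate_bilateral_traces(params)
    io.write_traces_csv(traces, OUT / f"traces_{label}.csv")
    truth.events.to_csv(OUT / f"traces_{label}_ground_truth.csv", index=False)
    print(f"traces_{label}.csv: {traces.n_frames} frames, "
          f"{len(truth)} ground-truth events")

# -- midlines: one straight and one curved cohort --------------------------
rng = np.random.default_rng(11)
axes = []
for i in range(40):
    curved = i < 8
    theta = rng.uniform(14.0, 45.0) if curved else rng.uniform(0.5, 6.0)
    axes.append(syn.simulate_midline(
        syn.MidlineSimParams(theta_deg=theta, n_points=41, noise_sd=0.01,
                             seed=500 + i),
        fish_id=f"fish{i:03d}", genotype="het" if curved or i % 2 else "wt",
        age_dpf=21))
io.write_midlines_csv(axes, OUT / "midlines.csv", OUT / "midlines_meta.csv")
print(f"midlines.csv: {len(axes)} fish")

# -- cohort allele counts ---------------------------------------------------
case, control = syn.simulate_cohort(syn.CohortSimParams(seed=21))
io.write_cohorts_csv([case, control], OUT / "cohort_counts.csv")
print(f"cohort_counts.csv: case {case.variant_alleles}/{case.total_alleles}, "
      f"control {control.variant_alleles}/{control.total_alleles}")

# -- sEMG -------------------------------------------------------------------
bursts = [syn.BurstSpec("left", s, 0.4, gain=5.0) for s in (0.8, 2.4, 3.9)]
rec = syn.simulate_semg(seed=31, burst_spec=bursts)
io.write_semg_csv(rec, OUT / "semg_standing.csv")
print(f"semg_standing.csv: {rec.n_samples} samples x {len(rec.channels)} channels")

# -- uptake plate -----------------------------------------------------------
rates = {"WT": 0.50, "vector": 0.02, "Y206F": 0.15, "R662W": 0.12,
         "G231S": 0.48, "S407G": 0.05, "K687R": 0.62}
plate = syn.simulate_uptake_plate(rates, noise_cv=0.08, seed=41)
io.write_plate_csv(plate, OUT / "uptake_plate.csv")
membrane = {"WT": 1.0, "vector": 0.05, "Y206F": 0.30, "R662W": 0.25,
            "G231S": 0.95, "S407G": 0.90, "K687R": 1.25}
io.write_membrane_csv(membrane, OUT / "membrane_levels.csv")
print(f"uptake_plate.csv: {len(plate.wells)} wells")

# -- gene sets --------------------------------------------------------------
rng = np.random.default_rng(51)
universe = [f"GENE{i:04d}" for i in range(400)]
sets = {f"pathway_{name}": list(rng.choice(universe, size, replace=False))
        for name, size in [("synapse", 30), ("cilium", 25), ("ecm", 40),
                           ("bone", 35), ("neuron_dev", 30)]}
write_gmt(sets, OUT / "annotation_sets.gmt")
synaptic = list(rng.choice(sets["pathway_synapse"], 12, replace=False))
background = list(rng.choice(universe, 28, replace=False))
(OUT / "query_genes.txt").write_text("\n".join(dict.fromkeys(synaptic + background)) + "\n")
print("annotation_sets.gmt + query_genes.txt written")
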