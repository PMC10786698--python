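#!/usr/bin/env python
"""Gene-set enrichment of a query list against GMT annotations.

Reads the annotation sets and query list written by 01_simulate_inputs.py
(the query was constructed with an excess of one pathway's members, the
way AIS-associated genes concentrate in synaptic pathways) and reports
hypergeometric enrichment with GeneRatio and BH-adjusted p-values.
"""

from pathlib import Path

from spinecpg import enrichment
from spinecpg.enrichment import GeneSetCollection

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs"
OUT = ROOT / "results"

sets = GeneSetCollection.from_gmt(INPUTS / "annotation_sets.gmt")
query = [g for g in (INPUTS / "query_genes.txt").read_text().split() if g]
table = enrichment.enrich(query, sets)
table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

print(f"query: {len(query)} genes, universe: {len(sets.universe)}, "
      f"unmapped: {len(table.attrs['unmapped_query_genes'])}")
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.4g}"))
top = table.iloc[0]
print(f"top set: {top['set_name']} (GeneRatio {top['gene_ratio']:.2f}, "
      f"adjusted p = {top['p_adjusted']:.3g})")
print(f"wrote {OUT / 'enrichment.tsv'}")
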