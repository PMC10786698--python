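"""Hypergeometric gene-set enrichment over user-supplied annotations.

For a query gene list and a collection of annotation sets (GMT), each set is
scored with the hypergeometric upper tail P(X >= k) for X ~
Hypergeom(N, K, n), where N is the universe size, K the set size, n the
number of query genes mapped to at least one set, and k the overlap.
GeneRatio is k/n. Raw p-values are Benjamini-Hochberg adjusted across sets.
The universe defaults to the union of all annotation-set members and is
overridable. No ontology is bundled; annotations are the caller's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ParameterError


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if any(len(s) == 0 for s in self.sets.values()):
            raise ParameterError("annotation sets must be nonempty")
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        self.universe = frozenset(self.universe)
        stray = frozenset().union(*self.sets.values()) - self.universe if self.sets else set()
        if stray:
            raise ParameterError(f"set members outside the universe: {sorted(stray)[:5]}...")

    @property
    def mapped_genes(self) -> frozenset[str]:
        return frozenset().union(*self.sets.values()) if self.sets else frozenset()

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParameterError(f"malformed GMT line: {line[:60]!r}")
                name, _description, *genes = fields
                genes = [g for g in genes if g]
                if not genes:
                    raise ParameterError(f"empty gene set {name!r}")
                sets[name] = frozenset(genes)
        return cls(sets=sets, universe=frozenset(universe) if universe else frozenset())


def write_gmt(collection: Mapping[str, Iterable[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def enrich(query: Iterable[str], sets: GeneSetCollection,
           universe: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-set enrichment table sorted by adjusted p.

    Columns: set_name, k, n, K, N, gene_ratio, p, p_adjusted. The frame
    carries ``attrs["unmapped_query_genes"]`` — query genes inside the
    universe but in no annotation set; they are reported but excluded from n.
    """
    uni = frozenset(universe) if universe is not None else sets.universe
    q = frozenset(query) & uni
    if not q:
        raise DegenerateInputError("no query genes inside the universe")
    mapped_q = q & sets.mapped_genes
    unmapped = sorted(q - sets.mapped_genes)
    n, big_n = len(mapped_q), len(uni)
    rows = []
    for name, members in sets.sets.items():
        members = members & uni
        k = len(mapped_q & members)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if n else 1.0
        rows.append({"set_name": name, "k": k, "n": n, "K": big_k, "N": big_n,
                     "gene_ratio": k / n if n else 0.0, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p_adjusted", "p"], kind="stable").reset_index(drop=True)
    else:
        df["p_adjusted"] = []
    df.attrs["unmapped_query_genes"] = unmapped
    return df
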