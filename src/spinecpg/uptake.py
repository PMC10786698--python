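"""Glycine-uptake assay normalization and group comparison.

Raw per-well uptake (nmol of glycine over an incubation) is converted to a
rate in nmol/min/mg protein, expressed as a percentage of the mean wild-type
rate, and optionally re-normalized by each genotype's relative cytomembrane
GLYT1 level (WT = 1) — if a variant's reduced uptake is fully explained by
reduced surface presentation, the membrane-normalized value returns to
parity with WT. Group comparison is a one-way ANOVA with per-variant
contrasts against WT under a declared multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

SPECIFIC_ACTIVITY_CI_PER_MMOL = 60.0  # [3H]-glycine stock
WELL_COLUMNS = ("well", "genotype", "nmol", "time_min", "protein_mg", "replicate")


@dataclass
class UptakePlate:
    """Per-well measurements: columns well, genotype, nmol, time_min,
    protein_mg, replicate."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        for col in WELL_COLUMNS:
            if col not in self.wells.columns:
                raise ParameterError(f"UptakePlate missing column {col!r}")
        if (self.wells["time_min"] <= 0).any() or (self.wells["protein_mg"] <= 0).any():
            raise ParameterError("incubation time and protein mass must be positive")
        if (self.wells["nmol"] < 0).any():
            raise ParameterError("uptake quantities must be nonnegative")

    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.wells["genotype"]))


def dpm_to_nmol(dpm: float, specific_activity_ci_per_mmol: float = SPECIFIC_ACTIVITY_CI_PER_MMOL,
                counting_efficiency: float = 1.0) -> float:
    """Convert scintillation counts (DPM) to nmol of glycine.

    1 Ci = 2.22e12 DPM; at 60 Ci/mmol, 1 nmol of tracer-labeled glycine
    corresponds to 2.22e12 * 60 / 1e6 DPM. ``counting_efficiency`` rescales
    CPM-style counts to true DPM.
    """
    if specific_activity_ci_per_mmol <= 0 or not 0 < counting_efficiency <= 1:
        raise ParameterError("invalid conversion constants")
    dpm_per_nmol = 2.22e12 * specific_activity_ci_per_mmol / 1e6
    return (dpm / counting_efficiency) / dpm_per_nmol


def uptake_rate(nmol, time_min, protein_mg):
    """Uptake rate in nmol/min/mg protein (vectorized)."""
    time_min = np.asarray(time_min, dtype=float)
    protein_mg = np.asarray(protein_mg, dtype=float)
    if np.any(time_min <= 0) or np.any(protein_mg <= 0):
        raise ParameterError("time and protein must be positive")
    return np.asarray(nmol, dtype=float) / (time_min * protein_mg)


def plate_rates(plate: UptakePlate) -> pd.DataFrame:
    """Per-well rates: the plate table plus a ``rate`` column."""
    df = plate.wells.copy()
    df["rate"] = uptake_rate(df["nmol"], df["time_min"], df["protein_mg"])
    return df


def percent_of_wt(rates: pd.DataFrame, wt_label: str = "WT") -> pd.DataFrame:
    """Express each well's rate as a percentage of the mean WT rate.

    ``rates`` must have ``genotype`` and ``rate`` columns (see
    :func:`plate_rates`). The WT group mean maps to 100% by construction.
    """
    if wt_label not in set(rates["genotype"]):
        raise ParameterError(f"no {wt_label!r} wells on the plate")
    wt_mean = rates.loc[rates["genotype"] == wt_label, "rate"].mean()
    if wt_mean <= 0:
        raise ParameterError("mean WT rate must be positive")
    out = rates.copy()
    out["percent_of_wt"] = 100.0 * out["rate"] / wt_mean
    return out


def membrane_normalized_uptake(pct: pd.DataFrame,
                               membrane: Mapping[str, float]) -> pd.DataFrame:
    """Divide percent-of-WT uptake by each genotype's relative cytomembrane
    protein level (WT = 1); equals percent-of-WT when all levels are 1."""
    missing = set(pct["genotype"]) - set(membrane)
    if missing:
        raise ParameterError(f"missing membrane levels for {sorted(missing)}")
    if any(membrane[g] <= 0 for g in set(pct["genotype"])):
        raise ParameterError("membrane levels must be positive")
    out = pct.copy()
    out["membrane_level"] = out["genotype"].map(membrane).astype(float)
    out["membrane_normalized_pct"] = out["percent_of_wt"] / out["membrane_level"]
    return out


@dataclass
class UptakeComparison:
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    contrasts: pd.DataFrame  # genotype, statistic, p_adjusted
    adjustment: str


def compare_to_wt(groups: Mapping[str, np.ndarray], wt_label: str = "WT",
                  adjustment: str = "dunnett") -> UptakeComparison:
    """One-way ANOVA across genotypes plus per-variant contrasts vs WT.

    ``adjustment`` is "dunnett" (many-to-one comparison against the WT
    control), "holm", or "none" (pairwise Student t tests, Holm-adjusted or
    raw); the method used is recorded in the result.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if wt_label not in arrays:
        raise ParameterError(f"no {wt_label!r} group")
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ParameterError("need >= 2 groups with >= 2 replicates each")
    res = stats.f_oneway(*arrays.values())
    k, n = len(arrays), sum(a.size for a in arrays.values())
    variants = [g for g in arrays if g != wt_label]
    if adjustment == "dunnett":
        dres = stats.dunnett(*[arrays[g] for g in variants], control=arrays[wt_label])
        contrasts = pd.DataFrame({"genotype": variants,
                                  "statistic": dres.statistic,
                                  "p_adjusted": dres.pvalue})
    elif adjustment in ("holm", "none"):
        tstats, pvals = [], []
        for g in variants:
            t = stats.ttest_ind(arrays[g], arrays[wt_label], equal_var=True)
            tstats.append(float(t.statistic))
            pvals.append(float(t.pvalue))
        if adjustment == "holm" and pvals:
            pvals = list(multipletests(pvals, method="holm")[1])
        contrasts = pd.DataFrame({"genotype": variants, "statistic": tstats,
                                  "p_adjusted": pvals})
    else:
        raise ParameterError(f"unknown adjustment {adjustment!r}")
    return UptakeComparison(anova_f=float(res.statistic), anova_df=(k - 1, n - k),
                            anova_p=float(res.pvalue), contrasts=contrasts,
                            adjustment=adjustment)
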