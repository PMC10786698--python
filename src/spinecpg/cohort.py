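"""Cohort allele-frequency and association statistics.

Variant allele frequencies are simple proportions over allele counts
(2 per diploid subject); case-control association on the resulting 2x2
allele table uses a two-sided Fisher's exact test, the standard choice for
rare variants. The plasma-glycine comparison between variant carriers and
controls is an unpaired Student's t test, optionally restricted to one
age stratum (the adolescent contrast is the informative one, since AIS
manifests during the pubertal growth spurt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError

AGE_CLASSES = ("preadolescent", "adolescent", "adult")


@dataclass
class CohortTable:
    """Variant/total allele counts for one group."""

    group: str
    variant_alleles: int
    total_alleles: int
    carriers: int | None = None
    subjects: int | None = None

    def __post_init__(self) -> None:
        if self.total_alleles <= 0:
            raise ParameterError("total_alleles must be positive")
        if not 0 <= self.variant_alleles <= self.total_alleles:
            raise ParameterError("variant_alleles must be in [0, total_alleles]")

    @property
    def reference_alleles(self) -> int:
        return self.total_alleles - self.variant_alleles


@dataclass
class AssociationResult:
    odds_ratio: float
    p_two_sided: float
    test_name: str
    table: tuple[tuple[int, int], tuple[int, int]]
    continuity_corrected: bool = False


def allele_frequency(table: CohortTable) -> float:
    """Variant allele frequency as a percentage (full precision; round for
    display with :func:`spinecpg.format_percent`)."""
    return 100.0 * table.variant_alleles / table.total_alleles


def case_frequency(cases_with_variant: int, total_cases: int) -> float:
    """Fraction of cases (or alleles — the counting unit is the caller's)
    carrying the variant, as a percentage."""
    if total_cases <= 0:
        raise ParameterError("total_cases must be positive")
    if not 0 <= cases_with_variant <= total_cases:
        raise ParameterError("cases_with_variant must be in [0, total_cases]")
    return 100.0 * cases_with_variant / total_cases


def association_test(case_table: CohortTable, control_table: CohortTable) -> AssociationResult:
    """Two-sided Fisher's exact test on the 2x2 allele table.

    p sums the hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one. The odds ratio is the
    cross-product; a Haldane-Anscombe 0.5 correction is applied only when a
    cell is zero, and flagged.
    """
    a, b = case_table.variant_alleles, case_table.reference_alleles
    c, d = control_table.variant_alleles, control_table.reference_alleles
    if (a + c) == 0 and (b + d) == 0:
        raise DegenerateInputError("all-zero margins; association undefined")
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    corrected = any(x == 0 for x in (a, b, c, d))
    if corrected:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return AssociationResult(odds_ratio=float(orr), p_two_sided=p,
                             test_name="fisher_exact_two_sided",
                             table=((a, b), (c, d)),
                             continuity_corrected=corrected)


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_sided: float
    n_per_group: dict


def glycine_group_compare(panel: pd.DataFrame, stratum: str | None = None) -> TTestResult:
    """Unpaired two-sided Student's t test of plasma glycine concentration,
    carriers vs controls.

    ``panel`` columns: subject, group ("carrier"/"control"), age_class,
    concentration. ``stratum`` restricts to one age class (e.g.
    "adolescent").
    """
    df = panel
    if stratum is not None:
        df = df[df["age_class"] == stratum]
    groups = {g: df.loc[df["group"] == g, "concentration"].to_numpy(dtype=float)
              for g in ("carrier", "control")}
    if any(v.size < 2 for v in groups.values()):
        raise ParameterError("need >= 2 observations per group in the stratum")
    res = stats.ttest_ind(groups["carrier"], groups["control"], equal_var=True)
    dof = groups["carrier"].size + groups["control"].size - 2
    return TTestResult(t=float(res.statistic), df=dof, p_two_sided=float(res.pvalue),
                       n_per_group={g: int(v.size) for g, v in groups.items()})
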