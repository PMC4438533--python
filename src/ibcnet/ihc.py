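"""Contingency-table statistics for the IHC validation cohort.

Tissue-microarray staining of the candidate master regulators is scored
per case as a percentage of positive tumour cells (positive marker call:
strictly more than 5% by default) plus a subcellular pattern (NFAT5:
cytoplasmic C, nuclear N, mixed N/C, or negative; beta-catenin: membranous
M, M/C, N/C, or negative). Phenotype-by-marker 2x2 tables are tested with
the chi-square statistic, by default with the Yates continuity correction
(the correction is guarded with max(0, .) so over-correction cannot
produce a negative statistic), and summarised with sensitivity,
specificity, PPV and NPV. Fisher's exact test is available as an
alternative for small cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy import stats

NFAT5_PATTERNS = ("C", "N", "N/C", "Neg")
BCATENIN_PATTERNS = ("M", "M/C", "N/C", "Neg")


@dataclass
class CaseStaining:
    case_id: str
    phenotype: str  # IBC | nIBC
    percent_positive_cells: float
    pattern: str

    def __post_init__(self) -> None:
        if self.phenotype not in ("IBC", "nIBC"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if not 0 <= self.percent_positive_cells <= 100:
            raise ValueError("percent_positive_cells must be in [0, 100]")


@dataclass
class Table2x2:
    """Counts with rows = group 1/2 (IBC/nIBC) and columns = outcome +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.n == 0:
            raise ValueError("table total must be > 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    yates: bool


@dataclass
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV in percent."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def call_marker_positivity(
    percent_positive_cells: float, cutoff_percent: float = 5.0
) -> str:
    """'positive' iff strictly more than `cutoff_percent` of cells stain."""
    if not 0 <= percent_positive_cells <= 100:
        raise ValueError("percent_positive_cells must be in [0, 100]")
    return "positive" if percent_positive_cells > cutoff_percent else "negative"


def dichotomize_bcatenin(pattern: str) -> str:
    """Beta-catenin activation state: M or Neg -> inactive, M/C or N/C -> active."""
    if pattern not in BCATENIN_PATTERNS:
        raise ValueError(f"unknown beta-catenin pattern {pattern!r}")
    return "inactive" if pattern in ("M", "Neg") else "active"


def nfat5_nuclear_indicator(pattern: str) -> str:
    """NFAT5 nuclear localisation: N or N/C -> nuclear, C or Neg -> non-nuclear."""
    if pattern not in NFAT5_PATTERNS:
        raise ValueError(f"unknown NFAT5 pattern {pattern!r}")
    return "nuclear" if pattern in ("N", "N/C") else "non-nuclear"


def chi_square_2x2(table: Table2x2, yates: bool = True) -> ChiSquareResult:
    """Chi-square test of association on a 2x2 table (1 df).

    statistic = n * max(0, |ad - bc| - yates * n/2)^2 /
    ((a+b)(c+d)(a+c)(b+d)); p is the upper chi-square tail.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square test undefined with a zero margin")
    n = table.n
    corr = n / 2 if yates else 0.0
    num = n * max(0.0, abs(a * d - b * c) - corr) ** 2
    statistic = num / np.prod(margins, dtype=float)
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=float(statistic), df=1, p=p, yates=yates)


def fisher_exact_2x2(table: Table2x2) -> float:
    """Two-sided Fisher exact p, an alternative for small cells."""
    return float(stats.fisher_exact(table.as_array())[1])


def diagnostic_metrics(table: Table2x2) -> DiagnosticMetrics:
    """Diagnostic performance of the marker (columns) for the phenotype (rows).

    sensitivity = a/(a+b), specificity = d/(c+d), PPV = a/(a+c),
    NPV = d/(b+d), each as a percentage.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    for name, denom in (
        ("sensitivity", a + b),
        ("specificity", c + d),
        ("ppv", a + c),
        ("npv", b + d),
    ):
        if denom == 0:
            raise ValueError(f"{name} undefined: zero denominator")
    return DiagnosticMetrics(
        sensitivity=100 * a / (a + b),
        specificity=100 * d / (c + d),
        ppv=100 * a / (a + c),
        npv=100 * d / (b + d),
    )


def crosstab(
    cases: Iterable[CaseStaining], outcome: Callable[[CaseStaining], bool]
) -> Table2x2:
    """Build the IBC/nIBC-by-outcome table from per-case staining records."""
    cases = list(cases)
    counts = {("IBC", True): 0, ("IBC", False): 0, ("nIBC", True): 0, ("nIBC", False): 0}
    for case in cases:
        counts[(case.phenotype, bool(outcome(case)))] += 1
    if counts[("IBC", True)] + counts[("IBC", False)] == 0:
        raise ValueError("no IBC cases")
    if counts[("nIBC", True)] + counts[("nIBC", False)] == 0:
        raise ValueError("no nIBC cases")
    return Table2x2(
        a=counts[("IBC", True)],
        b=counts[("IBC", False)],
        c=counts[("nIBC", True)],
        d=counts[("nIBC", False)],
    )


def round_percent(value: float, decimals: int = 1) -> float:
    """Round half-up to a fixed number of decimals (cohort-fraction reporting)."""
    factor = 10**decimals
    return float(np.floor(value * factor + 0.5) / factor)


# 2x2 counts from the IBC/nIBC tissue-microarray validation cohort
# (39 IBC / 82 nIBC cases). Rows: IBC, nIBC; columns: outcome +, outcome -.
# The beta-catenin subcellular table is a reconstruction: its denominators
# are the beta-catenin-positive cases (37 IBC / 66 nIBC), the only integer
# tables consistent with the published percentages.
VALIDATION_TABLES: dict[str, Table2x2] = {
    # NFAT5 positivity (>5% cells) by phenotype, all 121 cases
    "nfat5_positivity": Table2x2(27, 12, 16, 66),
    # nuclear or N/C NFAT5 among the 43 NFAT5-positive cases
    "nfat5_nuclear": Table2x2(19, 8, 2, 14),
    # NFAT5 positivity within SBR grade 1-2 cases (14 IBC / 56 nIBC)
    "nfat5_grade12": Table2x2(9, 5, 10, 46),
    # NFAT5 positivity within SBR grade 3 cases (22 IBC / 14 nIBC)
    "nfat5_grade3": Table2x2(16, 6, 2, 12),
    # active (M/C or N/C) beta-catenin among beta-catenin-positive cases
    "bcatenin_active": Table2x2(23, 14, 5, 61),
    # beta-catenin positivity (39 IBC / 80 evaluable nIBC)
    "bcatenin_positivity": Table2x2(37, 2, 66, 14),
    # E-cadherin positivity (39 IBC / 80 evaluable nIBC)
    "ecadherin_positivity": Table2x2(34, 5, 66, 14),
}
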