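"""Double-reader ageing quality assurance.

Two readers independently count growth rings in each sectioned colony.
This module cross-tabulates the paired reads into a square age-agreement
table, tests the table for symmetry about its diagonal (systematic
reader bias) with three chi-squared tests that differ only in how the
off-diagonal cells are pooled, and summarises between-reader precision
with percent agreement (PA), average percent error (APE) and the average
coefficient of variation (ACV).  For exactly two readers ACV = sqrt(2) *
APE, an algebraic identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datatypes import AgeRounding

__all__ = [
    "AgreementTable",
    "SymmetryTestResult",
    "PrecisionIndices",
    "build_agreement_table",
    "mcnemar_symmetry",
    "evans_hoenig_symmetry",
    "bowker_symmetry",
    "precision_indices",
    "consensus_age",
]


@dataclass
class AgreementTable:
    """Square age-by-age cross-tabulation of reader 1 against reader 2.

    ``n[i, j]`` counts pairs with reader-1 age ``ages[i]`` and reader-2
    age ``ages[j]``; "above the diagonal" means reader 2 > reader 1.
    """

    ages: np.ndarray  # ordered integer age classes
    n: np.ndarray     # square count matrix

    @property
    def total(self) -> int:
        return int(self.n.sum())


@dataclass
class SymmetryTestResult:
    name: str
    statistic: float
    df: int
    p: float


@dataclass
class PrecisionIndices:
    """Between-reader precision, all on the percent scale."""

    pa: float
    ape: float
    acv: float
    n_pairs: int


def build_agreement_table(reads: Iterable[tuple[int, int]]) -> AgreementTable:
    """Cross-tabulate paired age reads over the combined age range."""
    pairs = [(int(a), int(b)) for a, b in reads]
    if not pairs:
        raise ValueError("no read pairs")
    if any(a < 0 or b < 0 for a, b in pairs):
        raise ValueError("ages must be non-negative")
    lo = min(min(a, b) for a, b in pairs)
    hi = max(max(a, b) for a, b in pairs)
    ages = np.arange(lo, hi + 1)
    idx = {age: k for k, age in enumerate(ages)}
    n = np.zeros((len(ages), len(ages)), dtype=int)
    for a, b in pairs:
        n[idx[a], idx[b]] += 1
    return AgreementTable(ages=ages, n=n)


def mcnemar_symmetry(table: AgreementTable) -> SymmetryTestResult:
    """Maximally pooled symmetry test.

    Pools every cell above the diagonal into A and every cell below into
    B; chi2 = (A - B)^2 / (A + B) on 1 df, no continuity correction.
    """
    n = table.n
    a = int(np.triu(n, 1).sum())
    b = int(np.tril(n, -1).sum())
    if a + b == 0:
        raise ValueError("no disagreements; symmetry test undefined")
    chi2 = (a - b) ** 2 / (a + b)
    return SymmetryTestResult("mcnemar", float(chi2), 1, float(stats.chi2.sf(chi2, 1)))


def evans_hoenig_symmetry(table: AgreementTable) -> SymmetryTestResult:
    """Diagonally pooled symmetry test.

    Cells are pooled by their distance d = |i - j| from the diagonal;
    each distance with any disagreement contributes
    (A_d - B_d)^2 / (A_d + B_d) and one degree of freedom.
    """
    n = table.n
    k = n.shape[0]
    chi2 = 0.0
    df = 0
    for d in range(1, k):
        a_d = int(np.diagonal(n, offset=d).sum())
        b_d = int(np.diagonal(n, offset=-d).sum())
        if a_d + b_d > 0:
            chi2 += (a_d - b_d) ** 2 / (a_d + b_d)
            df += 1
    if df == 0:
        raise ValueError("perfect agreement; symmetry test undefined")
    return SymmetryTestResult("evans_hoenig", float(chi2), df, float(stats.chi2.sf(chi2, df)))


def bowker_symmetry(table: AgreementTable) -> SymmetryTestResult:
    """Unpooled (Bowker) symmetry test.

    Every unordered off-diagonal cell pair (i, j), i < j, with
    n_ij + n_ji > 0 contributes (n_ij - n_ji)^2 / (n_ij + n_ji) and one
    degree of freedom.
    """
    n = table.n
    k = n.shape[0]
    chi2 = 0.0
    df = 0
    for i in range(k):
        for j in range(i + 1, k):
            tot = n[i, j] + n[j, i]
            if tot > 0:
                chi2 += (n[i, j] - n[j, i]) ** 2 / tot
                df += 1
    if df == 0:
        raise ValueError("perfect agreement; symmetry test undefined")
    return SymmetryTestResult("bowker", float(chi2), df, float(stats.chi2.sf(chi2, df)))


def precision_indices(reads: Iterable[tuple[int, int]]) -> PrecisionIndices:
    """PA, APE and ACV for paired reads.

    Per colony with reads (x1, x2) and mean m: the APE term is
    (1/2) * (|x1 - m| + |x2 - m|) / m and the ACV term is sd / m with the
    two-read sample standard deviation (denominator 1).  APE and ACV are
    100 times the means of these terms over colonies; pairs with m = 0
    are excluded with a warning.
    """
    pairs = [(float(a), float(b)) for a, b in reads]
    if not pairs:
        raise ValueError("no read pairs")
    arr = np.asarray(pairs)
    means = arr.mean(axis=1)
    keep = means > 0
    if not keep.any():
        raise ValueError("all pairs have mean age 0")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} pair(s) with mean age 0 from APE/ACV")
    pa = 100.0 * float((arr[:, 0] == arr[:, 1]).mean())
    sub = arr[keep]
    m = means[keep]
    ape_terms = 0.5 * (np.abs(sub - m[:, None]).sum(axis=1)) / m
    sd = sub.std(axis=1, ddof=1)
    acv_terms = sd / m
    return PrecisionIndices(
        pa=pa,
        ape=100.0 * float(ape_terms.mean()),
        acv=100.0 * float(acv_terms.mean()),
        n_pairs=len(pairs),
    )


def consensus_age(read1: float, read2: float,
                  rule: AgeRounding | str = AgeRounding.HALF_EVEN) -> float:
    """Consensus age for a pair of reads: their mean, rounded per rule.

    When the reads differ by an odd number of years the mean falls on a
    half-year; ``half_even`` banker-rounds it, ``half_up``/``half_down``
    push it away from/toward zero, ``keep_fraction`` returns the raw mean.
    """
    rule = AgeRounding(rule)
    if read1 < 0 or read2 < 0:
        raise ValueError("ages must be non-negative")
    mean = (float(read1) + float(read2)) / 2.0
    if rule is AgeRounding.KEEP_FRACTION or mean == int(mean):
        return mean if rule is AgeRounding.KEEP_FRACTION else float(int(mean))
    if rule is AgeRounding.HALF_EVEN:
        return float(round(mean))  # Python round is banker's rounding
    if rule is AgeRounding.HALF_UP:
        return float(np.floor(mean) + 1)
    return float(np.floor(mean))


def consensus_ages(pairs: Sequence[tuple[int, int]],
                   rule: AgeRounding | str = AgeRounding.HALF_EVEN) -> np.ndarray:
    """Vectorised :func:`consensus_age` over a sequence of read pairs."""
    return np.array([consensus_age(a, b, rule) for a, b in pairs])
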