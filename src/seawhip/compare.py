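"""Between-site statistics: pairwise KS tests with Bonferroni control,
one-way ANOVA, and Tukey HSD.

Length and age distributions are compared pairwise between sites with
two-sample Kolmogorov–Smirnov tests; because only two sites enter one KS
test, all C(k, 2) pairs are tested and the family-wise alpha is divided
by the number of tests (Bonferroni).  Means are compared with one-way
ANOVA, followed by Tukey's HSD (Tukey–Kramer for unequal group sizes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import KSMode

__all__ = [
    "TestResult",
    "ComparisonBattery",
    "ks_two_sample",
    "bonferroni_alpha",
    "one_way_anova",
    "tukey_hsd",
    "site_battery",
]

EXACT_KS_LIMIT = 10_000  # n_x * n_y at or below this: exact p in auto mode


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    df: Optional[tuple] = None
    groups: tuple = ()


@dataclass
class ComparisonBattery:
    """All pairwise KS tests plus ANOVA and Tukey HSD over the sites."""

    ks: list[TestResult]
    adjusted_alpha: float
    anova: TestResult
    tukey: list[TestResult]
    family_wise_alpha: float = 0.05

    @property
    def n_ks_tests(self) -> int:
        return len(self.ks)

    def significant_ks(self) -> list[TestResult]:
        return [t for t in self.ks if t.p < self.adjusted_alpha]


def ks_two_sample(x: Sequence[float], y: Sequence[float],
                  mode: KSMode | str = KSMode.AUTO,
                  groups: tuple = ()) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_x - ECDF_y|.  In auto mode the p-value is exact when
    n_x * n_y <= 10,000 and asymptotic (Kolmogorov tail with effective-n
    scaling) otherwise.
    """
    mode = KSMode(mode)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode is KSMode.AUTO:
        method = "exact" if x.size * y.size <= EXACT_KS_LIMIT else "asymp"
    elif mode is KSMode.EXACT:
        method = "exact"
    else:
        method = "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return TestResult("ks", float(res.statistic), float(res.pvalue), groups=groups)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test critical alpha (unrounded)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def _group_arrays(groups: Mapping[str, Sequence[float]]):
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return names, arrays


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within, df (k-1, n-k)."""
    names, arrays = _group_arrays(groups)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        # all groups constant and equal: MS_within = 0
        return TestResult("anova", float("nan"), float("nan"),
                          df=(k - 1, n - k), groups=tuple(names))
    return TestResult("anova", float(f), float(p), df=(k - 1, n - k), groups=tuple(names))


def _ms_within(arrays) -> float:
    k = len(arrays)
    n = sum(a.size for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    return ssw / (n - k)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[TestResult]:
    """Tukey HSD pairwise comparisons (Tukey–Kramer for unequal n).

    q = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j)); p from
    the studentized-range upper tail with k groups and n - k error df.
    """
    names, arrays = _group_arrays(groups)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    msw = _ms_within(arrays)
    results = []
    for (gi, ai), (gj, aj) in itertools.combinations(zip(names, arrays), 2):
        se = np.sqrt(msw / 2.0 * (1.0 / ai.size + 1.0 / aj.size))
        if se == 0:
            q = 0.0 if ai.mean() == aj.mean() else float("inf")
        else:
            q = abs(ai.mean() - aj.mean()) / se
        p = float(stats.studentized_range.sf(q, k, n - k)) if np.isfinite(q) else 0.0
        results.append(TestResult("tukey_hsd", float(q), p, df=(k, n - k), groups=(gi, gj)))
    return results


def site_battery(groups: Mapping[str, Sequence[float]],
                 family_wise_alpha: float = 0.05,
                 ks_mode: KSMode | str = KSMode.AUTO) -> ComparisonBattery:
    """Full between-site battery on one variable.

    Runs all C(k, 2) pairwise KS tests with a Bonferroni-adjusted
    critical alpha, plus one-way ANOVA and Tukey HSD on the same groups.
    """
    names, arrays = _group_arrays(groups)
    pairs = list(itertools.combinations(range(len(names)), 2))
    adj = bonferroni_alpha(family_wise_alpha, len(pairs))
    ks = [
        ks_two_sample(arrays[i], arrays[j], mode=ks_mode, groups=(names[i], names[j]))
        for i, j in pairs
    ]
    return ComparisonBattery(
        ks=ks,
        adjusted_alpha=adj,
        anova=one_way_anova(groups),
        tukey=tukey_hsd(groups),
        family_wise_alpha=family_wise_alpha,
    )


def battery_table(battery: ComparisonBattery):
    """Flatten a battery into a tidy records list (test, groups, statistic,
    df, p, adjusted_alpha, significant)."""
    rows = []
    for t in battery.ks:
        rows.append(
            {
                "test": "ks",
                "groups": " vs ".join(t.groups),
                "statistic": t.statistic,
                "df": "",
                "p": t.p,
                "adjusted_alpha": battery.adjusted_alpha,
                "significant": t.p < battery.adjusted_alpha,
            }
        )
    a = battery.anova
    rows.append(
        {
            "test": "anova",
            "groups": " vs ".join(a.groups),
            "statistic": a.statistic,
            "df": f"{a.df[0]},{a.df[1]}",
            "p": a.p,
            "adjusted_alpha": battery.family_wise_alpha,
            "significant": a.p < battery.family_wise_alpha if np.isfinite(a.p) else False,
        }
    )
    for t in battery.tukey:
        rows.append(
            {
                "test": "tukey_hsd",
                "groups": " vs ".join(t.groups),
                "statistic": t.statistic,
                "df": f"{t.df[0]},{t.df[1]}",
                "p": t.p,
                "adjusted_alpha": battery.family_wise_alpha,
                "significant": t.p < battery.family_wise_alpha,
            }
        )
    return rows
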