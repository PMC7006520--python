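"""Age-length keys and Isermann–Knight age assignment.

An age-length key (ALK) gives, for each length bin, the proportion of
aged individuals at each integer age.  The *observed* key is the raw
cross-tabulation of the aged (collected) sample; the *smoothed* key
replaces those raw proportions with the fitted probabilities of a
multinomial logistic regression of age class on bin midpoint, which
borrows strength across bins and fills bins the aged sample missed.

Unaged (in-situ) individuals measured for length only receive ages via
the Isermann–Knight two-stage scheme: within each bin, each age first
receives the whole-number part of n_l * p_la individuals; the leftover
individuals are assigned one age each, drawn without replacement with
probabilities proportional to the fractional remainders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LengthBinning",
    "AgeLengthKey",
    "observed_alk",
    "smoothed_alk",
    "assign_ages_ik",
]


@dataclass
class LengthBinning:
    """Left-closed, right-open length bins [l, l + width) from an origin.

    With ``last_bin_all_inclusive`` the top occupied bin of a key also
    absorbs any longer individuals (used when the unaged sample extends
    beyond the aged sample's largest length category).
    """

    width_cm: float = 5.0
    origin_cm: float = 0.0
    last_bin_all_inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.width_cm > 0:
            raise ValueError("bin width must be > 0")

    def lower_bound(self, length_cm: float) -> float:
        k = np.floor((np.asarray(length_cm) - self.origin_cm) / self.width_cm)
        return self.origin_cm + k * self.width_cm

    def midpoint(self, lower: float) -> float:
        return lower + self.width_cm / 2.0


@dataclass
class AgeLengthKey:
    """Proportion-at-age matrix over length bins.

    ``p`` is indexed by bin lower bound (rows) and integer age (columns);
    occupied rows sum to 1.  ``n`` holds the aged sample size per bin
    (zero for bins only present via smoothing).
    """

    p: pd.DataFrame
    n: pd.Series
    binning: LengthBinning
    kind: str  # "observed" | "smoothed"

    @property
    def bins(self) -> np.ndarray:
        return self.p.index.to_numpy(dtype=float)

    @property
    def ages(self) -> np.ndarray:
        return self.p.columns.to_numpy(dtype=int)

    def validate(self) -> None:
        occupied = self.p.loc[self.n[self.n > 0].index] if self.kind == "observed" else self.p
        sums = occupied.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError("ALK rows must sum to 1")
        if ((self.p < -1e-12) | (self.p > 1 + 1e-12)).any().any():
            raise AssertionError("ALK proportions must lie in [0, 1]")


def _bin_ages(aged: Iterable[tuple[float, int]], binning: LengthBinning):
    pairs = [(float(l), int(a)) for l, a in aged]
    if not pairs:
        raise ValueError("no aged individuals")
    if any(a < 0 for _, a in pairs):
        raise ValueError("ages must be non-negative integers")
    lengths = np.array([l for l, _ in pairs])
    ages = np.array([a for _, a in pairs])
    lowers = binning.lower_bound(lengths)
    return lowers, ages


def observed_alk(aged: Iterable[tuple[float, int]], binning: LengthBinning) -> AgeLengthKey:
    """Raw cross-tabulated key: p[l, a] = n_la / n_l.

    Rows cover the full range of occupied bins; intermediate empty bins
    are kept as all-NaN rows (flagged empty, not zero-filled).
    """
    lowers, ages = _bin_ages(aged, binning)
    tab = pd.crosstab(lowers, ages)
    lo, hi = tab.index.min(), tab.index.max()
    full_bins = np.arange(lo, hi + binning.width_cm / 2, binning.width_cm)
    age_classes = np.arange(ages.min(), ages.max() + 1)
    tab = tab.reindex(index=full_bins, columns=age_classes, fill_value=0)
    n = tab.sum(axis=1)
    p = tab.div(n, axis=0)  # empty bins -> NaN rows
    p.index.name = "bin_lower_cm"
    p.columns.name = "age"
    return AgeLengthKey(p=p, n=n.astype(int), binning=binning, kind="observed")


def smoothed_alk(aged: Iterable[tuple[float, int]], binning: LengthBinning) -> AgeLengthKey:
    """Multinomial-logistic smoothed key.

    Age class is regressed on bin midpoint (single numeric covariate) by
    maximum likelihood with the youngest age as reference; fitted
    probabilities are returned for every bin in the occupied range,
    including bins with no aged individuals.  Complete separation is
    reported as a warning and the boundary-approaching fit returned.
    """
    lowers, ages = _bin_ages(aged, binning)
    uniq_ages = np.unique(ages)
    if uniq_ages.size < 2:
        raise ValueError("smoothing requires >= 2 distinct ages")
    if np.unique(lowers).size < 2:
        raise ValueError("smoothing requires >= 2 occupied bins")

    mid = np.array([binning.midpoint(l) for l in lowers])
    # standardised covariate keeps the optimiser well conditioned; the
    # fitted probabilities are invariant to this affine rescaling
    mu, sd = mid.mean(), mid.std()
    sd = sd if sd > 0 else 1.0
    # outcome coded 0..k-1 in age order; reference = youngest age
    code = {a: i for i, a in enumerate(uniq_ages)}
    y = np.array([code[a] for a in ages])
    X = sm.add_constant((mid - mu) / sd)
    model = sm.MNLogit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation / convergence chatter handled below
        res = model.fit(method="bfgs", maxiter=2000, gtol=1e-8, disp=0)
        if not res.mle_retvals.get("converged", True) or np.isnan(np.asarray(res.params)).any():
            res = model.fit(method="lbfgs", maxiter=5000, disp=0)
    if not res.mle_retvals.get("converged", True):
        warnings.warn(
            "multinomial fit did not fully converge (possible complete "
            "separation); returning boundary-approaching probabilities"
        )

    lo, hi = lowers.min(), lowers.max()
    full_bins = np.arange(lo, hi + binning.width_cm / 2, binning.width_cm)
    mids = np.array([binning.midpoint(b) for b in full_bins])
    probs = res.predict(sm.add_constant((mids - mu) / sd, has_constant="add"))
    p = pd.DataFrame(np.asarray(probs), index=full_bins, columns=uniq_ages)
    p.index.name = "bin_lower_cm"
    p.columns.name = "age"
    n = pd.Series(0, index=full_bins, name="n")
    obs_counts = pd.Series(lowers).value_counts()
    for b, c in obs_counts.items():
        n.loc[b] = int(c)
    return AgeLengthKey(p=p, n=n.astype(int), binning=binning, kind="smoothed")


def assign_ages_ik(
    unaged_lengths: Sequence[float],
    key: AgeLengthKey,
    seed: Optional[int | np.random.Generator] = None,
) -> pd.DataFrame:
    """Isermann–Knight age assignment for length-only individuals.

    Per bin with n unaged individuals and key row p: each age a first
    receives floor(n * p_a) individuals (deterministic stage); the
    remaining r = n - sum(floor) individuals each receive one age drawn
    without replacement with probability proportional to the fractional
    remainders (stochastic stage).  Which individual receives which age
    is uniform-random within the bin.  Lengths beyond the top key bin
    fall into it when the binning is last-bin-all-inclusive.

    Returns a DataFrame (index = position of the input length) with
    columns ``length_cm``, ``bin_lower_cm``, ``assigned_age``, ``stage``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.asarray(list(unaged_lengths), dtype=float)
    if lengths.size == 0:
        return pd.DataFrame(columns=["length_cm", "bin_lower_cm", "assigned_age", "stage"])

    binning = key.binning
    lowers = np.array([binning.lower_bound(l) for l in lengths])
    top = key.bins.max()
    if binning.last_bin_all_inclusive:
        lowers = np.minimum(lowers, top)

    usable = key.p.dropna(how="all")
    rows = {float(b): usable.loc[b] for b in usable.index}
    ages = key.ages

    out_age = np.empty(lengths.size, dtype=float)
    out_stage = np.empty(lengths.size, dtype=object)
    for b in np.unique(lowers):
        members = np.flatnonzero(lowers == b)
        if float(b) not in rows:
            raise ValueError(
                f"unaged individual(s) fall in bin {b:g} with no key row "
                "(and last bin not all-inclusive)"
            )
        p = rows[float(b)].to_numpy(dtype=float)
        n_l = members.size
        base = np.floor(n_l * p + 1e-12).astype(int)
        assigned = []
        stages = []
        for a, c in zip(ages, base):
            assigned.extend([a] * c)
            stages.extend(["deterministic"] * c)
        r = n_l - base.sum()
        if r > 0:
            frac = n_l * p - base
            frac = np.clip(frac, 0.0, None)
            extra = _draw_without_replacement(frac, r, rng)
            assigned.extend(ages[extra])
            stages.extend(["stochastic"] * r)
        perm = rng.permutation(n_l)
        for k, m in enumerate(members):
            out_age[m] = assigned[perm[k]]
            out_stage[m] = stages[perm[k]]

    return pd.DataFrame(
        {
            "length_cm": lengths,
            "bin_lower_cm": lowers,
            "assigned_age": out_age.astype(int),
            "stage": out_stage,
        }
    )


def _draw_without_replacement(weights: np.ndarray, r: int, rng: np.random.Generator) -> list[int]:
    """Draw r distinct indices with probability proportional to weights."""
    w = weights.astype(float).copy()
    picked: list[int] = []
    for _ in range(r):
        total = w.sum()
        if total <= 0:
            # remainders exhausted (can happen via float round-off): fall back
            # to uniform over ages not yet picked
            w = np.ones_like(w)
            w[picked] = 0.0
            total = w.sum()
        idx = int(rng.choice(len(w), p=w / total))
        picked.append(idx)
        w[idx] = 0.0
    return picked
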