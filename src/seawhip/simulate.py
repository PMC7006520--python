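"""Seeded generators for synthetic colonies.

Because no colony-level field data are distributed with this package,
these generators produce inputs with the statistical structure the
analysis modules assume: branching trees with a controllable bifurcation
ratio and tributary rate, and multi-site age-length populations drawn
from a von Bertalanffy growth curve with additive length noise and a
±1-year double-read disagreement structure.

Defaults emulate the mid-Atlantic sea-whip study conditions: a VBGF with
L_inf = 86.1 cm, K = 0.14 1/y, t0 = 1.44 y; ages 2–15 y with the middle
ages (6–8 y) holding most of the mass; 102 collected (aged) and 119
in-situ (length-only) colonies across four sites; an 18% chance that the
two readers disagree, always by one year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .datatypes import ColonyRecord, Context, Dataset
from .growth import VBGFParams, predict_length

__all__ = [
    "TreeGenSpec",
    "PopulationGenSpec",
    "gen_branch_trees",
    "gen_population",
    "DEFAULT_AGE_DISTRIBUTION",
]

# Age mass roughly matching the study's collected sample: quartiles at
# 6 and 8 y, ~14% younger than 6, ~22% older than 8, range 2-15 y.
DEFAULT_AGE_DISTRIBUTION: dict[int, float] = {
    2: 0.01, 3: 0.02, 4: 0.04, 5: 0.07,
    6: 0.24, 7: 0.22, 8: 0.18,
    9: 0.07, 10: 0.05, 11: 0.04, 12: 0.03, 13: 0.015, 14: 0.01, 15: 0.005,
}

DEFAULT_SITES = ("Memorial Barge", "South Ledges", "Sussex Wreck", "Boom Wreck")


@dataclass
class TreeGenSpec:
    """Specification for branching-tree generation.

    ``target_rb`` controls how many source branches each higher-order
    segment spawns: exactly ``target_rb`` when it is an integer,
    otherwise max(2, 1 + Poisson(target_rb - 1)) per segment.
    ``tributary_rate`` is the Poisson mean number of tributary branches
    attached along each higher-order segment (these do not promote the
    order, so they raise the realised R_b above ``target_rb``).
    """

    target_rb: float = 3.0
    max_order: int = 3
    tributary_rate: float = 0.0
    n_trees: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.target_rb < 1:
            raise ValueError("target_rb must be >= 1")
        if self.max_order < 2:
            raise ValueError("max_order must be >= 2")
        if self.tributary_rate < 0:
            raise ValueError("tributary_rate must be >= 0")


def _build_segment(order: int, spec: TreeGenSpec, rng: np.random.Generator,
                   counter: list[int]) -> dendropy.Node:
    """Build one order-`order` segment and its subtree; return its top node."""
    if order == 1:
        counter[0] += 1
        node = dendropy.Node()
        node._leaf_label = f"t{counter[0]}"
        return node
    if float(spec.target_rb).is_integer():
        c = max(2, int(spec.target_rb))
    else:
        c = max(2, 1 + int(rng.poisson(spec.target_rb - 1.0)))
    junction = dendropy.Node()
    for _ in range(c):
        junction.add_child(_build_segment(order - 1, spec, rng, counter))
    top = junction
    n_trib = int(rng.poisson(spec.tributary_rate))
    for _ in range(n_trib):
        wrapper = dendropy.Node()
        wrapper.add_child(top)
        wrapper.add_child(_build_segment(order - 1, spec, rng, counter))
        top = wrapper
    return top


def gen_branch_trees(spec: TreeGenSpec) -> list[dendropy.Tree]:
    """Generate rooted branch trees per the spec (bit-reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    trees = []
    for _ in range(spec.n_trees):
        counter = [0]
        root = _build_segment(spec.max_order, spec, rng, counter)
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = root
        for leaf in tree.leaf_node_iter():
            leaf.taxon = taxa.new_taxon(label=leaf._leaf_label)
        tree.is_rooted = True
        trees.append(tree)
    return trees


@dataclass
class PopulationGenSpec:
    """Specification for multi-site age-length populations.

    ``n`` is the number of collected (aged) colonies; ``n_in_situ``
    length-only colonies are generated in addition.  Lengths follow the
    VBGF at the colony's true age plus Normal(0, length_noise_sd),
    truncated below at 1 cm.  With probability ``read_error_prob`` the
    two reads of a collected colony disagree by exactly one year (one of
    the two readers is perturbed); ``read_bias`` is the probability that
    the disagreement has reader 2 older.  Per-site shifts move the
    length mean (cm) and the true age (whole years, clipped at 0).
    """

    n: int = 102
    n_in_situ: int = 119
    vbgf: VBGFParams = field(default_factory=lambda: VBGFParams(86.1, 0.14, 1.44))
    age_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    length_noise_sd: float = 5.0
    read_error_prob: float = 0.18
    read_bias: float = 0.5
    sites: tuple[str, ...] = DEFAULT_SITES
    site_length_shift: dict[str, float] = field(default_factory=dict)
    site_age_shift: dict[str, int] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        probs = np.array(list(self.age_distribution.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("age_distribution probabilities must sum to 1")
        if self.length_noise_sd < 0:
            raise ValueError("length_noise_sd must be >= 0")
        if not 0 <= self.read_error_prob <= 1:
            raise ValueError("read_error_prob must lie in [0, 1]")
        if not 0 <= self.read_bias <= 1:
            raise ValueError("read_bias must lie in [0, 1]")


def gen_population(spec: PopulationGenSpec) -> Dataset:
    """Generate a multi-site colony dataset (bit-reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    ages = np.array(list(spec.age_distribution), dtype=int)
    probs = np.array(list(spec.age_distribution.values()), dtype=float)
    probs = probs / probs.sum()

    records = []
    n_sites = len(spec.sites)

    def make_colony(i: int, context: Context) -> ColonyRecord:
        site = spec.sites[i % n_sites]
        true_age = int(rng.choice(ages, p=probs)) + int(spec.site_age_shift.get(site, 0))
        true_age = max(true_age, 0)
        mean_len = predict_length(spec.vbgf, true_age) + spec.site_length_shift.get(site, 0.0)
        if spec.length_noise_sd > 0:
            length = mean_len + rng.normal(0.0, spec.length_noise_sd)
            length = round(max(float(length), 1.0), 1)  # recorded to 0.1 cm
        else:
            length = max(float(mean_len), 1.0)  # exactly on the growth curve
        read1 = read2 = None
        if context is Context.COLLECTED:
            read1 = read2 = true_age
            if rng.random() < spec.read_error_prob:
                direction = 1 if rng.random() < spec.read_bias else -1
                if rng.random() < 0.5:
                    read1 = max(true_age - direction, 0)
                else:
                    read2 = max(true_age + direction, 0)
                # direction convention: positive => reader 2 reads older
        prefix = "C" if context is Context.COLLECTED else "IS"
        return ColonyRecord(
            site=site,
            colony_id=f"{prefix}{i + 1:04d}",
            total_length_cm=length,
            context=context,
            read1_age=read1,
            read2_age=read2,
        )

    for i in range(spec.n):
        records.append(make_colony(i, Context.COLLECTED))
    for i in range(spec.n_in_situ):
        records.append(make_colony(spec.n + i, Context.IN_SITU))

    return Dataset(records=records, provenance=f"synthetic population, seed={spec.seed}")
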