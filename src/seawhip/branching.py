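"""Colony complexity: Strahler-style branch ordering, bifurcation and T/S ratios.

Branch orders follow the stream-network convention adapted to arborescent
octocorals: the most distal branches are first order (primary); where two
or more branches of equal order meet, they form a branch of the next
higher order and are called *source* branches; a branch that joins a
branch of higher order is a *tributary* and does not promote the order.

A "branch" is a maximal path of segments sharing one order, so an
order-w branch may run through several junctions where tributaries
attach.  The bifurcation ratio R_b summarises how fast branch counts
decay with order: it is the antilog of the (absolute) slope of the OLS
regression of log10(branch count) on order.  A perfectly dichotomous
colony has R_b = 2; tributaries push it higher.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .datatypes import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "OrderSummary",
    "ComplexityResult",
    "assign_orders",
    "bifurcation_ratio",
    "ts_ratio",
    "site_complexity",
]


@dataclass
class OrderSummary:
    """Per-order branch counts and tributary/source tallies for one colony."""

    counts: dict[int, int]
    tributaries: dict[int, int] = field(default_factory=dict)
    sources: dict[int, int] = field(default_factory=dict)

    @property
    def max_order(self) -> int:
        return max(self.counts)


def assign_orders(tree: dendropy.Tree) -> OrderSummary:
    """Assign Strahler-style orders to a branch tree and tally branches.

    Rules, applied bottom-up from the distal tips:

    * tip segments have order 1;
    * where k >= 2 children share the maximal child order m, the parent
      segment takes order m + 1 and those k children are *sources*; any
      lower-order children at that junction are *tributaries*;
    * where the maximal child order m is unique, the parent continues the
      same order-m branch and every lower-order child is a *tributary*.

    A branch (one unit of the per-order count N_w) is a maximal
    constant-order path; the continuation child in the unique-maximum
    case belongs to its parent's branch and is not counted again.
    """
    root = tree.seed_node
    if root is None:
        raise ValueError("empty tree")

    order: dict[dendropy.Node, int] = {}
    counts: dict[int, int] = {}
    tributaries: dict[int, int] = {}
    sources: dict[int, int] = {}

    # postorder: children before parents
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            order[node] = 1
            continue
        child_orders = [order[c] for c in children]
        m = max(child_orders)
        n_max = child_orders.count(m)
        if n_max >= 2:
            order[node] = m + 1
            for c in children:
                w = order[c]
                if w == m:
                    sources[w] = sources.get(w, 0) + 1
                else:
                    tributaries[w] = tributaries.get(w, 0) + 1
        else:
            order[node] = m
            for c in children:
                w = order[c]
                if w < m:
                    tributaries[w] = tributaries.get(w, 0) + 1
                # the unique order-m child continues this branch

    # count branch heads: nodes whose parent has a different order (or no parent)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        w = order[node]
        if parent is None or order[parent] != w:
            counts[w] = counts.get(w, 0) + 1

    return OrderSummary(counts=counts, tributaries=tributaries, sources=sources)


def bifurcation_ratio(summary: OrderSummary, base: float = 10.0) -> float:
    """Bifurcation ratio R_b from the log-linear decay of branch counts.

    OLS fit of log_base(N_w) on w over w = 1..max_order; returns
    base**|slope|.  The result is independent of the choice of base.
    """
    if summary.max_order < 2:
        raise ValueError("bifurcation ratio undefined for unbranched colony")
    if base <= 1:
        raise ValueError("log base must exceed 1")
    orders = np.arange(1, summary.max_order + 1, dtype=float)
    n_w = np.array([summary.counts[int(w)] for w in orders], dtype=float)
    logs = np.log(n_w) / np.log(base)
    slope = np.polyfit(orders, logs, 1)[0]
    return float(base ** abs(slope))


def ts_ratio(summary: OrderSummary, order: int) -> float:
    """Tributary/source ratio at a branch order (1 = primary, 2 = secondary)."""
    if order not in (1, 2):
        raise ValueError("T/S ratio is computed for orders 1 and 2 only")
    s = summary.sources.get(order, 0)
    if s == 0:
        raise ValueError(f"undefined T/S at order {order}: no source branches")
    return summary.tributaries.get(order, 0) / s


@dataclass
class ComplexityResult:
    """Per-colony complexity measures and their per-site means."""

    per_colony: pd.DataFrame  # site, colony_id, r_b, ts_primary, ts_secondary
    site_means: pd.DataFrame  # site, n, r_b, ts_primary, ts_secondary


def site_complexity(dataset: Dataset) -> ComplexityResult:
    """R_b and T/S per colony with arithmetic site means.

    Colonies whose tree does not support a statistic (unbranched for R_b,
    no sources at an order for T/S) are excluded from that statistic's
    mean and logged.
    """
    rows = []
    for rec in dataset.records:
        if rec.tree_id is None:
            continue
        summary = assign_orders(dataset.trees[rec.tree_id])
        row: dict = {"site": rec.site, "colony_id": rec.colony_id}
        try:
            row["r_b"] = bifurcation_ratio(summary)
        except ValueError as exc:
            logger.info("colony %s: %s", rec.colony_id, exc)
            row["r_b"] = math.nan
        for name, w in (("ts_primary", 1), ("ts_secondary", 2)):
            try:
                row[name] = ts_ratio(summary, w)
            except ValueError as exc:
                logger.info("colony %s: %s", rec.colony_id, exc)
                row[name] = math.nan
        rows.append(row)
    per_colony = pd.DataFrame(rows, columns=["site", "colony_id", "r_b", "ts_primary", "ts_secondary"])
    if per_colony.empty:
        raise ValueError("no colonies with branch trees")
    grouped = per_colony.groupby("site", sort=False)
    site_means = grouped.agg(
        n=("colony_id", "size"),
        r_b=("r_b", "mean"),
        ts_primary=("ts_primary", "mean"),
        ts_secondary=("ts_secondary", "mean"),
    ).reset_index()
    empty_sites = site_means[site_means["r_b"].isna() & (site_means["n"] > 0)]
    for site in empty_sites["site"]:
        logger.warning("site %s: no colony supported a bifurcation ratio", site)
    return ComplexityResult(per_colony=per_colony, site_means=site_means)
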