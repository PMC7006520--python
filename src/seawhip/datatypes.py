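"""Core domain types for colony demography analyses.

A *colony record* is one measured sea-whip colony: where it was sampled,
its stretched total length, whether it was collected (and hence aged by
counting skeletal growth rings) or only measured in situ, and — for
collected colonies — the two independent ring-count reads.  Branch
architecture travels separately as rooted trees keyed by ``tree_id``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd

__all__ = [
    "Context",
    "ColonyRecord",
    "Dataset",
    "AnalysisConfig",
    "DataValidationError",
]


class DataValidationError(ValueError):
    """A record or file violates a domain invariant."""


class Context(str, enum.Enum):
    """How a colony was measured: collected to the lab, or in situ."""

    COLLECTED = "collected"
    IN_SITU = "in_situ"


@dataclass
class ColonyRecord:
    """One measured colony.

    Parameters
    ----------
    site : str
        Site label (free string; comparisons run over all declared sites).
    colony_id : str
        Unique identifier within the dataset.
    total_length_cm : float
        Stretched total length (holdfast to most distal tip), cm, > 0.
    context : Context
        ``collected`` colonies may carry paired ring-count reads;
        ``in_situ`` colonies carry length only.
    read1_age, read2_age : int, optional
        Independent ring counts (years) by the two readers.  Either both
        present or both absent; present only for collected colonies.
    tree_id : str, optional
        Key of this colony's branch tree in :attr:`Dataset.trees`.
    """

    site: str
    colony_id: str
    total_length_cm: float
    context: Context
    read1_age: Optional[int] = None
    read2_age: Optional[int] = None
    tree_id: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.context, str):
            self.context = Context(self.context)
        if not self.total_length_cm > 0:
            raise DataValidationError(
                f"colony {self.colony_id!r}: total_length_cm must be > 0, "
                f"got {self.total_length_cm}"
            )
        has1, has2 = self.read1_age is not None, self.read2_age is not None
        if has1 != has2:
            raise DataValidationError(
                f"colony {self.colony_id!r}: paired reads required "
                "(read1_age and read2_age must both be present or both absent)"
            )
        if has1:
            if self.context is not Context.COLLECTED:
                raise DataValidationError(
                    f"colony {self.colony_id!r}: age reads are only valid for "
                    "collected colonies"
                )
            for name, val in (("read1_age", self.read1_age), ("read2_age", self.read2_age)):
                if int(val) != val or val < 0:
                    raise DataValidationError(
                        f"colony {self.colony_id!r}: {name} must be a "
                        f"non-negative integer, got {val}"
                    )
            self.read1_age = int(self.read1_age)
            self.read2_age = int(self.read2_age)

    @property
    def has_reads(self) -> bool:
        return self.read1_age is not None


@dataclass
class Dataset:
    """A collection of colony records plus their branch trees."""

    records: list[ColonyRecord] = field(default_factory=list)
    trees: dict[str, dendropy.Tree] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        # with no trees attached, tree_id fields are opaque references
        # (stages that need topology load the trees and re-validate)
        if not self.trees:
            return
        for rec in self.records:
            if rec.tree_id is not None and rec.tree_id not in self.trees:
                raise DataValidationError(
                    f"colony {rec.colony_id!r}: tree_id {rec.tree_id!r} does "
                    "not resolve to a tree in this dataset"
                )

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.site, None)
        return list(seen)

    def subset(self, context: Context | str) -> "Dataset":
        context = Context(context)
        recs = [r for r in self.records if r.context is context]
        return Dataset(records=recs, trees=self.trees, provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "site": r.site,
                    "colony_id": r.colony_id,
                    "total_length_cm": r.total_length_cm,
                    "context": r.context.value,
                    "read1_age": r.read1_age,
                    "read2_age": r.read2_age,
                    "tree_id": r.tree_id,
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "site",
                "colony_id",
                "total_length_cm",
                "context",
                "read1_age",
                "read2_age",
                "tree_id",
            ],
        )
        return df

    def aged_pairs(self) -> pd.DataFrame:
        """(length, read1, read2) for every colony carrying paired reads."""
        rows = [
            (r.colony_id, r.site, r.total_length_cm, r.read1_age, r.read2_age)
            for r in self.records
            if r.has_reads
        ]
        return pd.DataFrame(
            rows, columns=["colony_id", "site", "total_length_cm", "read1_age", "read2_age"]
        )


class AgeRounding(str, enum.Enum):
    """How half-year consensus ages are resolved to integers."""

    HALF_EVEN = "half_even"
    HALF_UP = "half_up"
    HALF_DOWN = "half_down"
    KEEP_FRACTION = "keep_fraction"


class KSMode(str, enum.Enum):
    AUTO = "auto"
    EXACT = "exact"
    ASYMPTOTIC = "asymptotic"


@dataclass
class AnalysisConfig:
    """Pipeline-wide settings.

    Defaults follow the study conventions: 5-cm length bins from 0,
    family-wise alpha 0.05 (Bonferroni-divided across the KS battery),
    1000 bootstrap replicates for growth-parameter CIs.
    """

    length_bin_width_cm: float = 5.0
    length_bin_origin_cm: float = 0.0
    family_wise_alpha: float = 0.05
    bootstrap_replicates: int = 1000
    rng_seed: int = 0
    age_rounding_rule: AgeRounding = AgeRounding.HALF_EVEN
    ks_mode: KSMode = KSMode.AUTO

    def __post_init__(self) -> None:
        if isinstance(self.age_rounding_rule, str):
            self.age_rounding_rule = AgeRounding(self.age_rounding_rule)
        if isinstance(self.ks_mode, str):
            self.ks_mode = KSMode(self.ks_mode)
        if not self.length_bin_width_cm > 0:
            raise DataValidationError("length_bin_width_cm must be > 0")
        if not 0 < self.family_wise_alpha < 1:
            raise DataValidationError("family_wise_alpha must be in (0, 1)")
        if self.bootstrap_replicates < 1:
            raise DataValidationError("bootstrap_replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "length_bin_width_cm": self.length_bin_width_cm,
            "length_bin_origin_cm": self.length_bin_origin_cm,
            "family_wise_alpha": self.family_wise_alpha,
            "bootstrap_replicates": self.bootstrap_replicates,
            "rng_seed": self.rng_seed,
            "age_rounding_rule": self.age_rounding_rule.value,
            "ks_mode": self.ks_mode.value,
        }
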