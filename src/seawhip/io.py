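"""Readers and writers: colony CSV, Newick branch trees, config, result bundles.

CSV dialect is fixed: comma-separated, UTF-8, header required, '.' decimal
mark.  Branch architecture travels as rooted Newick trees whose leaves are
the distal branch tips; polytomies are preserved.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping, Optional

import dendropy
import pandas as pd
import yaml

from .datatypes import AnalysisConfig, ColonyRecord, Context, Dataset, DataValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site", "colony_id", "total_length_cm", "context")
OPTIONAL_COLUMNS = ("read1_age", "read2_age", "tree_id")


def _opt_int(value: Any) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    f = float(value)
    if f != int(f):
        raise DataValidationError(f"expected integer age, got {value}")
    return int(f)


def read_colony_csv(path: str | Path, trees: Optional[dict[str, dendropy.Tree]] = None) -> Dataset:
    """Read a colony table into a validated :class:`Dataset`.

    Rows violating record invariants are rejected with row-numbered
    diagnostics (row numbers count data rows from 1, header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"site": str, "colony_id": str, "tree_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path.name}: missing required column(s) {missing}")

    records = []
    errors = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            length = float(getattr(row, "total_length_cm"))
            if math.isnan(length):
                raise DataValidationError("total_length_cm is missing")
            rec = ColonyRecord(
                site=str(getattr(row, "site")),
                colony_id=str(getattr(row, "colony_id")),
                total_length_cm=length,
                context=Context(str(getattr(row, "context"))),
                read1_age=_opt_int(getattr(row, "read1_age", None)),
                read2_age=_opt_int(getattr(row, "read2_age", None)),
                tree_id=(
                    str(getattr(row, "tree_id"))
                    if getattr(row, "tree_id", None) not in (None, "")
                    and not (isinstance(getattr(row, "tree_id"), float) and math.isnan(getattr(row, "tree_id")))
                    else None
                ),
            )
        except (DataValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    if errors:
        raise DataValidationError(f"{path.name}: " + "; ".join(errors))
    return Dataset(records=records, trees=trees or {}, provenance=f"read from {path.name}")


def write_colony_csv(dataset: Dataset, path: str | Path) -> None:
    df = dataset.to_dataframe()
    # keep ages as nullable integers so a round-trip is field-for-field exact
    for col in ("read1_age", "read2_age"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


def read_branch_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted branch tree from a Newick file.

    Leaves are distal branch tips and must be uniquely labelled; internal
    nodes of degree >= 2 (polytomies) are preserved.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise DataValidationError(f"{path.name}: invalid Newick: {exc}") from exc
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise DataValidationError(f"{path.name}: all leaves must be labelled")
    if len(set(labels)) != len(labels):
        raise DataValidationError(f"{path.name}: duplicate leaf labels")
    tree.is_rooted = True
    return tree


def read_branch_newick_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string; see :func:`read_branch_newick`."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise DataValidationError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise DataValidationError("all leaves must be labelled")
    if len(set(labels)) != len(labels):
        raise DataValidationError("duplicate leaf labels")
    tree.is_rooted = True
    return tree


def read_tree_directory(dirpath: str | Path, pattern: str = "*.nwk") -> dict[str, dendropy.Tree]:
    """Read every Newick file in a directory; tree_id = file stem."""
    dirpath = Path(dirpath)
    return {p.stem: read_branch_newick(p) for p in sorted(dirpath.glob(pattern))}


def write_tree_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise DataValidationError(f"{path.name}: config must be a mapping")
    return AnalysisConfig.from_dict(dict(data))


def write_results(bundle: Mapping[str, Any], outdir: str | Path,
                  config: Optional[AnalysisConfig] = None,
                  seed: Optional[int] = None) -> list[Path]:
    """Write a stage's outputs to ``outdir`` plus a JSON run manifest.

    DataFrames become CSV files named after their bundle key; mappings and
    scalars are collected into ``results.json``.  The manifest records the
    config and seed so a stage can be re-run identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scalars: dict[str, Any] = {}
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            p = outdir / f"{key}.csv"
            value.to_csv(p, index=False)
            written.append(p)
        else:
            scalars[key] = value
    if scalars:
        p = outdir / "results.json"
        p.write_text(json.dumps(scalars, indent=2, default=str))
        written.append(p)
    if not bundle:
        logger.warning("empty result bundle: writing manifest only")
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "outputs": [p.name for p in written],
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    written.append(mp)
    return written
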