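"""Readers and writers for delimited tables and newick trees.

All downstream modules consume the domain types from :mod:`adenomet.data_model`;
nothing else in the package touches files.  TSV vs CSV is autodetected by file
extension; blanks and the tokens ``NA``/``NaN`` (case-insensitive) are read as
not-detected cells.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import (
    FeatureTable,
    MetaboliteAnnotation,
    SampleMetadata,
    validate_tree,
)

logger = logging.getLogger(__name__)

NA_TOKENS = {"", "na", "nan"}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(
    path: str | Path, orientation: str = "samples_in_rows"
) -> FeatureTable:
    """Read a delimited samples x features table.

    Parameters
    ----------
    path : str
        TSV or CSV file; first column holds row ids, header holds column ids.
    orientation : {"samples_in_rows", "features_in_rows"}
        Layout of the file; the returned table is always samples x features.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    if orientation == "features_in_rows":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column ids")
    raw = df.to_numpy()
    detected = np.ones(raw.shape, dtype=bool)
    values = np.zeros(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell.lower() in NA_TOKENS:
                detected[i, j] = False
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r}: {cell!r}"
                    ) from exc
    return FeatureTable(
        values=values,
        detected=detected,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        scale_tag="raw",
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable; not-detected cells are written as ``NA``."""
    df = table.to_frame(masked=True)
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_annotation(path: str | Path) -> MetaboliteAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    truthy = {"true", "1", "yes"}
    df["identity_known"] = df["identity_known"].str.lower().isin(truthy)
    return MetaboliteAnnotation(df)


def write_annotation(annot: MetaboliteAnnotation, path: str | Path) -> None:
    annot.frame.to_csv(path, sep=_sep_for(path), index_label="feature_id")


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted newick tree with branch lengths; validates invariants."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def read_newick_string(newick: str) -> TreeNode:
    tree = TreeNode.read(_io.StringIO(newick), format="newick")
    return validate_tree(tree)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_manifest(path: str | Path, config: dict, seed: int,
                   extra: dict | None = None) -> None:
    """Write a machine-readable run manifest (config + seed) next to results."""
    payload = {"seed": int(seed), "config": config}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def validate_dataset(
    metab: FeatureTable,
    annot: MetaboliteAnnotation,
    micro: FeatureTable,
    meta: SampleMetadata,
) -> dict:
    """Cross-check the four inputs and report inconsistencies.

    Report-only, except an empty sample intersection across the two omics
    blocks and the metadata, which is a hard error (nothing downstream can
    run).
    """
    issues: list[str] = []
    metab_s = set(metab.sample_ids)
    micro_s = set(micro.sample_ids)
    meta_s = set(meta.sample_ids)
    shared = metab_s & micro_s & meta_s
    if not shared:
        raise ValueError("empty sample-id intersection across omics blocks and metadata")
    unannotated = sorted(set(metab.feature_ids) - set(annot.feature_ids))
    if unannotated:
        issues.append(
            f"{len(unannotated)} metabolites lack annotation (unknown identity): "
            + ", ".join(unannotated[:5])
        )
    unknown = set(annot.feature_ids) - set(annot.known_ids())
    flagged = sorted(set(metab.feature_ids) & unknown)
    if flagged:
        issues.append(f"{len(flagged)} metabolites have unknown identity")
    report = {
        "n_shared_samples": len(shared),
        "n_metab_only_samples": len(metab_s - shared),
        "n_micro_only_samples": len(micro_s - shared),
        "n_meta_only_samples": len(meta_s - shared),
        "n_unannotated_features": len(unannotated),
        "issues": issues,
    }
    for issue in issues:
        logger.warning("validate_dataset: %s", issue)
    return report


def aligned_sample_ids(*objs) -> list[str]:
    """Ordered intersection of sample ids across tables/metadata.

    Order follows the first argument; used by every cross-omics operation.
    """
    sets = []
    for o in objs[1:]:
        sets.append(set(o.sample_ids))
    return [s for s in objs[0].sample_ids if all(s in t for t in sets)]
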