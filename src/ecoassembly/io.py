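"""Readers, writers and rarefaction for the formats the pipeline touches.

OTU tables are accepted as TSV (taxa in rows by default, the common
QIIME/mothur export layout) or BIOM-JSON (format 1.0); trees as Newick;
metadata as TSV with the sample id in the first column. Dropped samples and
default-filled branch lengths are logged rather than silently accepted.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ecoassembly.containers import OtuTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "rarefy",
]

#: Rarefaction depth used throughout the motivating study; always overridable.
DEFAULT_RAREFACTION_DEPTH = 30_892


def read_otu_table(
    path,
    format: str = "tsv",
    taxa_as_rows: bool = True,
    round: bool = False,
    taxonomy_column: str | None = "taxonomy",
) -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"tsv", "biom-json"}
        TSV dialect: first column taxon id (or sample id when
        ``taxa_as_rows=False``), remaining columns counts. BIOM-JSON is the
        plain-JSON BIOM 1.0 interchange format.
    taxa_as_rows : bool
        TSV orientation flag; ignored for BIOM.
    round : bool
        Round non-integer counts instead of rejecting them.
    taxonomy_column : str or None
        Name of an optional trailing TSV column holding lineage strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        frame.index = frame.index.astype(str)
        taxonomy = None
        if taxonomy_column is not None and taxonomy_column in frame.columns:
            taxonomy = frame[taxonomy_column].astype(str)
            frame = frame.drop(columns=[taxonomy_column])
        if taxa_as_rows:
            counts = frame.T
        else:
            counts = frame
            taxonomy = None
        if not round:
            arr = counts.to_numpy()
            if np.issubdtype(arr.dtype, np.floating) and not np.allclose(
                arr, np.round(arr)
            ):
                raise ValueError(
                    f"{path}: non-integer counts (pass round=True to round)"
                )
        else:
            counts = counts.astype(float).round()
        return OtuTable(counts, taxonomy=taxonomy)
    elif format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format: {format!r}")


def write_otu_table(
    table: OtuTable, path, format: str = "tsv", taxa_as_rows: bool = True
) -> None:
    """Write an OTU table as TSV or BIOM-JSON (inverse of `read_otu_table`)."""
    path = Path(path)
    if format == "tsv":
        frame = table.counts.T if taxa_as_rows else table.counts
        if taxa_as_rows and table.taxonomy is not None:
            frame = frame.copy()
            frame["taxonomy"] = table.taxonomy
        frame.index.name = "#OTU ID" if taxa_as_rows else "#Sample ID"
        frame.to_csv(path, sep="\t")
    elif format == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def _read_biom_json(path: Path) -> OtuTable:
    """Minimal BIOM 1.0 (JSON) reader: dense or sparse, taxa-as-rows layout."""
    with open(path) as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    taxonomy = None
    meta = [r.get("metadata") for r in doc["rows"]]
    if any(m and "taxonomy" in m for m in meta):
        taxonomy = pd.Series(
            [
                "; ".join(m["taxonomy"]) if m and m.get("taxonomy") else ""
                for m in meta
            ],
            index=taxon_ids,
        )
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=taxon_ids)
    return OtuTable(counts, taxonomy=taxonomy)


def _write_biom_json(table: OtuTable, path: Path) -> None:
    mat = table.counts.to_numpy().T  # BIOM rows = taxa
    rows = []
    for tid in table.taxon_ids:
        md = None
        if table.taxonomy is not None:
            lineage = table.taxonomy.get(tid)
            if isinstance(lineage, str) and lineage:
                md = {"taxonomy": [s.strip() for s in lineage.split(";")]}
        rows.append({"id": tid, "metadata": md})
    data = [
        [int(i), int(j), int(mat[i, j])]
        for i, j in zip(*np.nonzero(mat))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "ecoassembly",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(rows), table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_tree(path, default_branch_length: float | None = None) -> TreeNode:
    """Read a rooted Newick tree.

    Missing branch lengths raise unless ``default_branch_length`` is given
    (then they are filled with a logged warning). A basal trifurcation is
    treated as an unrooted tree and rerooted at the midpoint, with a warning.
    """
    tree = TreeNode.read(str(path), convert_underscores=False)
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            n_missing += 1
            if default_branch_length is None:
                raise ValueError(
                    f"{path}: branch without length (pass "
                    "default_branch_length to fill)"
                )
            node.length = default_branch_length
    if n_missing:
        msg = (
            f"{path}: filled {n_missing} missing branch lengths with "
            f"{default_branch_length}"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    for node in tree.traverse(include_self=False):
        if node.length < 0:
            raise ValueError(f"{path}: negative branch length")
    if len(tree.children) > 2:
        msg = f"{path}: basal multifurcation; rerooting at midpoint"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        tree = tree.root_at_midpoint()
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV: header row, sample id in the first column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path) -> None:
    frame = metadata.frame.copy()
    frame.index.name = frame.index.name or "sample_id"
    frame.to_csv(path, sep="\t")


def rarefy(
    table: OtuTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed=None
) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (logged). Sampling is
    multivariate hypergeometric per sample, reproducible under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.depth
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning(
            "rarefy: dropped %d samples below depth %d: %s",
            len(dropped),
            depth,
            dropped,
        )
    if len(keep) == 0:
        raise ValueError(f"no sample has >= {depth} reads")
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts.to_numpy())
    for i, row in enumerate(sub.counts.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=sub.sample_ids, columns=sub.taxon_ids)
    groups = sub.groups
    return OtuTable(counts, taxonomy=sub.taxonomy, groups=groups)
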