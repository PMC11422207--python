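"""Core in-memory containers: OTU count tables and sample metadata.

Counts are stored as integers; relative abundances are computed on demand and
never stored, so repeated normalisation cannot drift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "SampleMetadata"]


class OtuTable:
    """An integer OTU count matrix (samples x taxa) with ids and labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index = sample ids, columns = taxon ids.
    taxonomy : pandas.Series, optional
        Per-taxon lineage strings, indexed by taxon id.
    groups : pandas.Series, optional
        Per-sample categorical label (e.g. month), indexed by sample id.
    """

    def __init__(self, counts, taxonomy=None, groups=None):
        counts = pd.DataFrame(counts)
        if counts.size == 0:
            raise ValueError("OTU table is empty")
        if counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate taxon ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError(
                    "counts must be integral (pass round=True at read time "
                    "to round)"
                )
            counts = counts.round().astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        self.counts = counts
        if taxonomy is not None:
            taxonomy = pd.Series(taxonomy)
            taxonomy.index = taxonomy.index.astype(str)
            taxonomy = taxonomy.reindex(counts.columns)
        self.taxonomy = taxonomy
        if groups is not None:
            groups = pd.Series(groups)
            groups.index = groups.index.astype(str)
            missing = set(counts.index) - set(groups.index)
            if missing:
                raise ValueError(f"groups missing for samples: {sorted(missing)}")
            groups = groups.reindex(counts.index)
        self.groups = groups

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> pd.Series:
        """Per-sample row sum (reads)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised counts. Zero-depth samples yield all-zero rows."""
        d = self.depth.to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts.to_numpy() / d[:, None]
        rel[d == 0] = 0.0
        return pd.DataFrame(rel, index=self.counts.index, columns=self.counts.columns)

    # -- subsetting ------------------------------------------------------
    def select_samples(self, sample_ids) -> "OtuTable":
        sub = self.counts.loc[list(sample_ids)]
        groups = self.groups.loc[list(sample_ids)] if self.groups is not None else None
        return OtuTable(sub, taxonomy=self.taxonomy, groups=groups)

    def select_taxa(self, taxon_ids) -> "OtuTable":
        sub = self.counts[list(taxon_ids)]
        tax = self.taxonomy.loc[list(taxon_ids)] if self.taxonomy is not None else None
        return OtuTable(sub, taxonomy=tax, groups=self.groups)

    def groupby(self):
        """Yield (group label, OtuTable restricted to that group)."""
        if self.groups is None:
            raise ValueError("table has no group labels")
        for label in pd.unique(self.groups):
            ids = self.groups.index[self.groups == label]
            yield label, self.select_samples(ids)

    def __repr__(self):
        g = "" if self.groups is None else f", {self.groups.nunique()} groups"
        return f"<OtuTable: {self.n_samples} samples x {self.n_taxa} taxa{g}>"

    def __eq__(self, other):
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts)


class SampleMetadata:
    """Per-sample metadata: group labels, environmental covariates, coordinates.

    A thin, validated wrapper around a DataFrame indexed by sample id.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame)
        frame.index = frame.index.astype(str)
        if frame.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def numeric_columns(self) -> list[str]:
        return [
            c
            for c in self.frame.columns
            if np.issubdtype(self.frame[c].dtype, np.number)
        ]

    def matches(self, table: OtuTable) -> bool:
        return set(table.sample_ids) <= set(self.frame.index)

    def align_to(self, table: OtuTable) -> "SampleMetadata":
        if not self.matches(table):
            missing = set(table.sample_ids) - set(self.frame.index)
            raise ValueError(f"metadata missing samples: {sorted(missing)}")
        return SampleMetadata(self.frame.loc[table.sample_ids])

    def __repr__(self):
        return f"<SampleMetadata: {len(self.frame)} samples x {self.frame.shape[1]} columns>"
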