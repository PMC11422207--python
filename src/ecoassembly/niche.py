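"""Levins niche breadth, Pianka overlap, and habitat generalist/specialist
classification against a fixed-fixed permutation null.

Breadth B_j = 1 / sum_i P_ij^2 where P_ij is the share of taxon j's reads
found in sample i: B runs from 1 (all reads in one sample) to n_samples
(perfectly even use of every sample). The null permutes the count table
while preserving every row and column total exactly: the default scheme
randomises individual reads across samples (the Patefield r2dtable
distribution, under which every read is exchangeable), which is calibrated
-- on tables that really are one multinomial per sample it calls the
nominal ~5% of taxa. A serial unit-transfer Markov chain over 2x2
submatrices (the count analogue of quasiswap, uniform over
margin-preserving tables) is available as ``scheme="swap"``. Taxa whose
observed breadth exceeds the null's 97.5th percentile are generalists,
those below the 2.5th specialists, the rest neutralists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecoassembly.containers import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "levins_breadth",
    "niche_overlap",
    "permute_counts_fixed_fixed",
    "classify_spec_gen",
    "NicheBreadthModel",
    "NicheResults",
]


def _breadth_from_matrix(mat: np.ndarray) -> np.ndarray:
    """Levins B per column of a samples x taxa count matrix (NaN for empty)."""
    totals = mat.sum(axis=0, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = mat / totals
        b = 1.0 / (P**2).sum(axis=0)
    b[totals == 0] = np.nan
    return b


def levins_breadth(table: OtuTable) -> tuple[pd.Series, float]:
    """Per-taxon Levins breadth and the community mean Bcom.

    Taxa with zero total counts are dropped with a log message. B is
    invariant to scaling a taxon's counts by a constant.
    """
    b = _breadth_from_matrix(table.counts.to_numpy())
    series = pd.Series(b, index=table.taxon_ids)
    n_empty = int(series.isna().sum())
    if n_empty:
        logger.info("levins_breadth: dropped %d empty taxa", n_empty)
        series = series.dropna()
    return series, float(series.mean())


def niche_overlap(table: OtuTable, method: str = "pianka") -> pd.DataFrame:
    """Pairwise niche overlap matrix (symmetric, unit diagonal).

    Pianka's symmetric index:
    O_jk = sum_i P_ij P_ik / sqrt(sum_i P_ij^2 * sum_i P_ik^2).
    """
    if method != "pianka":
        raise ValueError("only method='pianka' is implemented")
    if table.n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    mat = table.counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    keep = totals > 0
    P = mat[:, keep] / totals[keep]
    gram = P.T @ P
    norms = np.sqrt(np.diag(gram))
    O = gram / np.outer(norms, norms)
    ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    return pd.DataFrame(O, index=ids, columns=ids)


def permute_counts_fixed_fixed(
    mat: np.ndarray, rng: np.random.Generator, n_swaps: int | None = None
) -> np.ndarray:
    """One fixed-fixed permutation of a count matrix (margins preserved).

    A serial Markov chain of unit transfers on random 2x2 submatrices
    [[a, b], [c, d]] -> [[a-1, b+1], [c+1, d-1]] (or the reverse), each of
    which leaves all row and column sums unchanged. ``n_swaps`` counts
    attempted moves (default: 5x the number of nonzero cells).
    """
    out = mat.copy()
    n_rows, n_cols = out.shape
    if n_swaps is None:
        n_swaps = 5 * int((out > 0).sum())
    rows = rng.integers(0, n_rows, size=(n_swaps, 2))
    cols = rng.integers(0, n_cols, size=(n_swaps, 2))
    direction = rng.random(n_swaps) < 0.5
    for t in range(n_swaps):
        r1, r2 = rows[t]
        c1, c2 = cols[t]
        if r1 == r2 or c1 == c2:
            continue
        if direction[t]:
            if out[r1, c1] > 0 and out[r2, c2] > 0:
                out[r1, c1] -= 1
                out[r1, c2] += 1
                out[r2, c1] += 1
                out[r2, c2] -= 1
        else:
            if out[r1, c2] > 0 and out[r2, c1] > 0:
                out[r1, c2] -= 1
                out[r1, c1] += 1
                out[r2, c2] += 1
                out[r2, c1] -= 1
    return out


def patefield_shuffle(
    mat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One fixed-fixed permutation by randomising reads across samples.

    Every read keeps its taxon label; sample membership is reshuffled
    uniformly. Row and column totals are preserved exactly and the
    resulting table follows the multivariate hypergeometric (Patefield
    r2dtable) distribution.
    """
    rows = mat.sum(axis=1)
    cols = mat.sum(axis=0)
    reads = np.repeat(np.arange(mat.shape[1]), cols)
    rng.shuffle(reads)
    out = np.empty_like(mat)
    start = 0
    for i, r in enumerate(rows):
        out[i] = np.bincount(reads[start : start + r], minlength=mat.shape[1])
        start += r
    return out


def classify_spec_gen(
    table: OtuTable,
    reps: int = 1000,
    seed=None,
    scheme: str = "hypergeometric",
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """Generalist / specialist / neutralist calls from the breadth null.

    ``scheme`` selects the fixed-fixed null: "hypergeometric" (reads
    randomisation; calibrated type-I behaviour) or "swap" (unit-transfer
    chain, uniform over margin-preserving tables). Returns a per-taxon
    frame with observed B, the null 95% interval and the class. A
    single-sample table is degenerate: everything is neutralist, with a
    warning.
    """
    if reps < 100:
        raise ValueError("need reps >= 100 for a stable 95% interval")
    mat = table.counts.to_numpy()
    obs = _breadth_from_matrix(mat)
    if table.n_samples < 2:
        warnings.warn("single-sample table: all taxa neutralist")
        return pd.DataFrame(
            {
                "breadth": obs,
                "null_lower": obs,
                "null_upper": obs,
                "class": "neutralist",
            },
            index=table.taxon_ids,
        )
    rng = np.random.default_rng(seed)
    row_sums = mat.sum(axis=1)
    col_sums = mat.sum(axis=0)
    nonempty = col_sums > 0
    null = np.empty((reps, int(nonempty.sum())))
    current = mat[:, nonempty]
    sub_cols = current.sum(axis=0)
    if scheme not in ("hypergeometric", "swap"):
        raise ValueError(f"unknown null scheme: {scheme!r}")
    for r in range(reps):
        if scheme == "hypergeometric":
            current = patefield_shuffle(mat[:, nonempty], rng)
        else:
            current = permute_counts_fixed_fixed(current, rng, n_swaps=n_swaps)
        assert np.array_equal(current.sum(axis=1), row_sums)
        assert np.array_equal(current.sum(axis=0), sub_cols)
        null[r] = _breadth_from_matrix(current)
    lower = np.full(mat.shape[1], np.nan)
    upper = np.full(mat.shape[1], np.nan)
    lower[nonempty] = np.percentile(null, 2.5, axis=0)
    upper[nonempty] = np.percentile(null, 97.5, axis=0)
    cls = np.where(
        obs > upper, "generalist", np.where(obs < lower, "specialist", "neutralist")
    )
    cls = np.where(np.isnan(obs), "neutralist", cls)
    return pd.DataFrame(
        {
            "breadth": obs,
            "null_lower": lower,
            "null_upper": upper,
            "class": cls,
        },
        index=table.taxon_ids,
    )


class NicheBreadthModel:
    """Niche breadth/overlap analysis of one OTU table (optionally per group)."""

    def __init__(self, table: OtuTable):
        self.table = table

    def fit(self, reps: int = 1000, seed=None) -> "NicheResults":
        breadth, bcom = levins_breadth(self.table)
        overlap = niche_overlap(self.table)
        classes = classify_spec_gen(self.table, reps=reps, seed=seed)
        return NicheResults(
            breadth=breadth, bcom=bcom, overlap=overlap, classes=classes
        )


@dataclass
class NicheResults:
    breadth: pd.Series = field(repr=False)
    bcom: float = 0.0
    overlap: pd.DataFrame = field(default=None, repr=False)
    classes: pd.DataFrame = field(default=None, repr=False)

    def class_counts(self) -> pd.Series:
        return (
            self.classes["class"]
            .value_counts()
            .reindex(["generalist", "specialist", "neutralist"], fill_value=0)
        )

    def summary(self) -> str:
        cc = self.class_counts()
        mean_overlap = float(
            self.overlap.to_numpy()[
                np.triu_indices(len(self.overlap), k=1)
            ].mean()
        )
        return "\n".join(
            [
                "Levins niche breadth",
                f"  taxa: {len(self.breadth)}   community mean B = "
                f"{self.bcom:.3f}   mean Pianka overlap = {mean_overlap:.3f}",
                f"  generalists: {cc['generalist']}   specialists: "
                f"{cc['specialist']}   neutralists: {cc['neutralist']}",
            ]
        )
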