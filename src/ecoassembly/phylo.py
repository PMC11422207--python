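"""Phylogenetic distance machinery shared by betaMNTD and the null models.

The null model is taxa-label shuffling on the patristic distance matrix
(the "taxa.labels" randomisation): the matrix is computed once and each
randomisation only permutes its rows and columns jointly, so a full null run
costs O(reps * n^2) instead of reps tree traversals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = ["patristic_matrix", "shuffle_tips", "shuffle_index"]


def patristic_matrix(tree: TreeNode, taxon_ids=None) -> pd.DataFrame:
    """Sum-of-branch-length distances between all tips, as a labelled frame.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted tree with branch lengths.
    taxon_ids : sequence of str, optional
        Restrict and order the matrix to these tips; all must be tips of the
        tree.
    """
    dm = tree.tip_tip_distances()
    frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    if taxon_ids is not None:
        missing = set(taxon_ids) - set(frame.index)
        if missing:
            raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]}")
        frame = frame.loc[list(taxon_ids), list(taxon_ids)]
    return frame


def shuffle_index(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random permutation of 0..n-1 (the tip-label shuffle)."""
    return rng.permutation(n)


def shuffle_tips(dist: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Jointly permute rows and columns by a uniform random tip permutation.

    The distance multiset (and the eigenvalue spectrum) is preserved; only
    which tip carries which distances changes. This is the unit null draw
    behind the betaNTI z-score.
    """
    rng = np.random.default_rng(seed)
    perm = shuffle_index(len(dist), rng)
    arr = dist.to_numpy()[np.ix_(perm, perm)]
    return pd.DataFrame(arr, index=dist.index, columns=dist.columns)
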