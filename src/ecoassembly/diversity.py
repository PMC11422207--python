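"""Alpha diversity, taxonomic beta-dissimilarity, and Mantel tests.

Conventions follow the mothur/vegan lineage of microbiome practice: Shannon
in natural log, bias-corrected Chao1 (the F2+1 form, defined at F2 = 0),
Faith PD including the root stem, Bray-Curtis on relative abundances and
Jaccard on presence/absence, and a one-sided (greater) Mantel permutation p.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode

from ecoassembly.containers import OtuTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "alpha_diversity",
    "faith_pd",
    "beta_matrix",
    "mantel",
    "euclidean_distance",
    "environment_distance",
]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _chao1(row: np.ndarray) -> float:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _shannon(row: np.ndarray) -> float:
    total = row.sum()
    if total == 0:
        return 0.0
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def _goods_coverage(row: np.ndarray) -> float:
    total = row.sum()
    if total == 0:
        return 0.0
    return 1.0 - (row == 1).sum() / total


def faith_pd(row: pd.Series, tree: TreeNode) -> float:
    """Total branch length of the rooted subtree spanning the present taxa.

    The path from each present tip up to the root is included (root stem
    counted), so PD for a single-taxon sample is that tip's root-to-tip
    path length.
    """
    present = set(row.index[np.asarray(row) > 0])
    if not present:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    missing = present - set(tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]}")
    counted: set[int] = set()
    total = 0.0
    for name in present:
        node = tips[name]
        while node.parent is not None and id(node) not in counted:
            counted.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample Chao1, Shannon (nats), Good's coverage and optionally Faith PD.

    Empty samples produce an all-zero record with a warning rather than an
    error, so a rarefied table with a degenerate sample still summarises.
    """
    counts = table.counts
    records = {}
    for sid in table.sample_ids:
        row = counts.loc[sid].to_numpy()
        if row.sum() == 0:
            warnings.warn(f"sample {sid} is empty; zero alpha record")
            rec = {"chao1": 0.0, "shannon": 0.0, "goods_coverage": 0.0}
            if tree is not None:
                rec["faith_pd"] = 0.0
            records[sid] = rec
            continue
        rec = {
            "chao1": _chao1(row),
            "shannon": _shannon(row),
            "goods_coverage": _goods_coverage(row),
        }
        if tree is not None:
            rec["faith_pd"] = faith_pd(counts.loc[sid], tree)
        records[sid] = rec
    return pd.DataFrame.from_dict(records, orient="index").loc[table.sample_ids]


# ---------------------------------------------------------------------------
# beta dissimilarity
# ---------------------------------------------------------------------------

def beta_matrix(table: OtuTable, metric: str = "bray") -> DistanceMatrix:
    """Pairwise Bray-Curtis (on relative abundances) or Jaccard (binary).

    Both are bounded in [0, 1], zero on identical samples and one on
    disjoint ones.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.depth == 0).any():
        bad = list(table.depth.index[table.depth == 0])
        raise ValueError(f"zero-total samples have undefined distance: {bad}")
    if metric == "bray":
        data = squareform(pdist(table.relative_abundance().to_numpy(), "braycurtis"))
    elif metric == "jaccard":
        data = squareform(pdist(table.counts.to_numpy() > 0, "jaccard"))
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return DistanceMatrix(data, ids=table.sample_ids)


def euclidean_distance(values, ids=None) -> DistanceMatrix:
    """Euclidean distances between samples on one or more numeric columns."""
    frame = pd.DataFrame(values)
    if ids is None:
        ids = [str(i) for i in frame.index]
    data = squareform(pdist(frame.to_numpy(dtype=float), "euclidean"))
    return DistanceMatrix(data, ids=list(ids))


def environment_distance(
    metadata: SampleMetadata, columns=None
) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental covariates."""
    cols = columns if columns is not None else metadata.numeric_columns()
    frame = metadata.frame[list(cols)].astype(float)
    z = (frame - frame.mean()) / frame.std(ddof=0).replace(0, 1)
    return euclidean_distance(z, ids=metadata.sample_ids)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _condensed_ranks(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(square matrix of condensed-entry ranks, condensed rank vector)."""
    v = dm.condensed_form()
    r = rankdata(v)
    return squareform(r), r


def _spearman_from_ranks(r1: np.ndarray, r2: np.ndarray) -> float:
    r1c = r1 - r1.mean()
    r2c = r2 - r2.mean()
    denom = np.sqrt((r1c**2).sum() * (r2c**2).sum())
    if denom == 0:
        return np.nan
    return float((r1c * r2c).sum() / denom)


def _partial_r(r12: float, r1c: float, r2c: float) -> float:
    denom = np.sqrt((1 - r1c**2) * (1 - r2c**2))
    if denom == 0:
        return np.nan
    return (r12 - r1c * r2c) / denom


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    control: DistanceMatrix | None = None,
    seed=None,
) -> tuple[float, float]:
    """Mantel (or partial Mantel, with ``control``) rank correlation test.

    r is the Spearman correlation of the off-diagonal upper triangles; the
    one-sided p-value is (1 + #{permuted r >= observed r}) / (1 +
    permutations), permuting the sample labels of ``d1`` jointly on rows and
    columns. With ``control`` the first-order partial correlation is tested,
    holding the control distances fixed.

    Because a label permutation only rearranges which unordered pair carries
    which distance, the rank multiset of each matrix is permutation-
    invariant; ranks are computed once and gathered per permutation, making
    dense permutation counts cheap. ``permutations="exact"`` enumerates all
    n! label permutations (p = #{r_perm >= r_obs} / n!, the identity
    included); feasible for small n only.
    """
    if method != "spearman":
        raise ValueError("only method='spearman' is supported")
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share ids and ordering")
    if control is not None and list(control.ids) != list(d1.ids):
        raise ValueError("control matrix must share ids and ordering")
    n = len(d1.ids)
    rng = np.random.default_rng(seed)

    R1, r1 = _condensed_ranks(d1)
    _, r2 = _condensed_ranks(d2)
    rc = _condensed_ranks(control)[1] if control is not None else None

    r12 = _spearman_from_ranks(r1, r2)
    if control is None:
        r_obs = r12
    else:
        r_obs = _partial_r(
            r12,
            _spearman_from_ranks(r1, rc),
            _spearman_from_ranks(r2, rc),
        )
    if permutations == 0 or np.isnan(r_obs):
        return r_obs, np.nan

    iu = np.triu_indices(n, k=1)
    if permutations == "exact":
        import itertools
        import math

        if math.factorial(n) > 500_000:
            raise ValueError("exact Mantel enumeration infeasible for this n")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.asarray(perm)
            g = R1[np.ix_(perm, perm)][iu]
            r12p = _spearman_from_ranks(g, r2)
            if control is None:
                rp = r12p
            else:
                rp = _partial_r(
                    r12p,
                    _spearman_from_ranks(g, rc),
                    _spearman_from_ranks(r2, rc),
                )
            total += 1
            if rp >= r_obs - 1e-12:
                count += 1
        return r_obs, count / total

    z2 = r2 - r2.mean()
    s2 = np.sqrt((z2**2).sum())
    if control is not None:
        zc = rc - rc.mean()
        sc = np.sqrt((zc**2).sum())
        r_2c = _spearman_from_ranks(r2, rc)
    mean1 = r1.mean()
    s1 = np.sqrt(((r1 - mean1) ** 2).sum())

    count_ge = 0
    chunk = 250
    done = 0
    while done < permutations:
        k = min(chunk, permutations - done)
        perms = np.stack([rng.permutation(n) for _ in range(k)])
        # gather permuted upper triangles of the rank matrix of d1
        gathered = R1[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
        g = gathered - mean1
        r12p = g @ z2 / (s1 * s2)
        if control is None:
            rp = r12p
        else:
            r1cp = g @ zc / (s1 * sc)
            rp = (r12p - r1cp * r_2c) / np.sqrt(
                (1 - r1cp**2) * (1 - r_2c**2)
            )
        count_ge += int((rp >= r_obs).sum())
        done += k
    p = (1 + count_ge) / (1 + permutations)
    return r_obs, p
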