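"""Ecological-process inference from pairwise community turnover.

The chain: observed betaMNTD (abundance-weighted mean distance from each
taxon to its nearest relative in the partner community) is z-scored against
a tip-label-shuffling null to give betaNTI; pairs not dominated by selection
(|betaNTI| < 2) are further split with the Bray-Curtis Raup-Crick metric
(RC_bray), whose null assembles communities probabilistically from the
regional pool while preserving each sample's richness and read total.
Each pair then receives exactly one of five process labels:

* variable selection        betaNTI > 2
* homogeneous selection     betaNTI < -2
* dispersal limitation      |betaNTI| < 2 and RC_bray >= 0.95
* homogenizing dispersal    |betaNTI| < 2 and RC_bray <= -0.95
* undominated               |betaNTI| < 2 and |RC_bray| < 0.95

Boundary convention: betaNTI of exactly +/-2 is not selection (the quoted
inequalities are strict); |RC| exactly 0.95 goes to the dispersal classes.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecoassembly.containers import OtuTable
from ecoassembly.diversity import beta_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "bmntd",
    "bnti",
    "rc_bray",
    "classify_process",
    "summarize_processes",
    "AssemblyModel",
    "AssemblyResults",
    "PROCESSES",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _bmntd_arrays(
    D: np.ndarray,
    f_j: np.ndarray,
    f_k: np.ndarray,
    idx_j: np.ndarray,
    idx_k: np.ndarray,
) -> float:
    """betaMNTD from a distance matrix and the two present-taxon index sets."""
    sub = D[np.ix_(idx_j, idx_k)]
    term_j = f_j @ sub.min(axis=1)
    term_k = f_k @ sub.min(axis=0)
    return 0.5 * (term_j + term_k)


def _pair_arrays(table: OtuTable, dist: pd.DataFrame, pair, weighted: bool):
    j, k = pair
    order = list(dist.index)
    counts = table.counts[order]
    row_j = counts.loc[j].to_numpy(dtype=float)
    row_k = counts.loc[k].to_numpy(dtype=float)
    if row_j.sum() == 0 or row_k.sum() == 0:
        raise ValueError(f"empty sample in pair ({j}, {k})")
    idx_j = np.flatnonzero(row_j)
    idx_k = np.flatnonzero(row_k)
    if weighted:
        f_j = row_j[idx_j] / row_j.sum()
        f_k = row_k[idx_k] / row_k.sum()
    else:
        f_j = np.full(len(idx_j), 1.0 / len(idx_j))
        f_k = np.full(len(idx_k), 1.0 / len(idx_k))
    return dist.to_numpy(), f_j, f_k, idx_j, idx_k


def bmntd(
    table: OtuTable, dist: pd.DataFrame, pair, weighted: bool = True
) -> float:
    """Beta mean-nearest-taxon distance between one sample pair.

    With ``weighted`` (default) each present taxon contributes its relative
    abundance; otherwise taxa contribute equally (1/S). Identical
    compositions give 0: every taxon's nearest neighbour in the other
    sample is itself.
    """
    D, f_j, f_k, idx_j, idx_k = _pair_arrays(table, dist, pair, weighted)
    return float(_bmntd_arrays(D, f_j, f_k, idx_j, idx_k))


def bnti(
    table: OtuTable,
    dist: pd.DataFrame,
    pair,
    reps: int = 999,
    seed=None,
    weighted: bool = True,
) -> float:
    """betaNTI: z-score of observed betaMNTD against the tip-shuffling null.

    Returns NaN (with a warning) when the null has zero spread, e.g. a
    star-like distance matrix where every shuffle gives the same betaMNTD.
    """
    rng = np.random.default_rng(seed)
    D, f_j, f_k, idx_j, idx_k = _pair_arrays(table, dist, pair, weighted)
    obs = _bmntd_arrays(D, f_j, f_k, idx_j, idx_k)
    n = D.shape[0]
    null = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(n)
        null[r] = _bmntd_arrays(D, f_j, f_k, perm[idx_j], perm[idx_k])
    sd = null.std(ddof=0)
    if sd == 0:
        warnings.warn(
            f"degenerate null for pair {pair}: all shuffled betaMNTD equal; "
            "betaNTI undefined"
        )
        return float("nan")
    return float((obs - null.mean()) / sd)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _bray(u: np.ndarray, v: np.ndarray) -> float:
    pu = u / u.sum()
    pv = v / v.sum()
    return float(1.0 - np.minimum(pu, pv).sum())


def _null_choices(
    richness: int,
    occupancy_p: np.ndarray,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """reps x richness taxon draws, each a weighted sample w/o replacement.

    Uses the Gumbel top-k construction: taking the k largest of
    log(w_i) + Gumbel noise is equivalent to k successive draws
    proportional to w without replacement.
    """
    with np.errstate(divide="ignore"):
        logw = np.log(occupancy_p)
    keys = logw[None, :] + rng.gumbel(size=(reps, len(occupancy_p)))
    return np.argpartition(-keys, richness - 1, axis=1)[:, :richness]


def rc_bray(
    table: OtuTable,
    pair,
    reps: int = 999,
    seed=None,
    pool: OtuTable | None = None,
    exact: bool = False,
) -> float:
    """Bray-Curtis-based Raup-Crick: where the observed dissimilarity sits in
    a null distribution of probabilistically assembled pairs, rescaled to
    [-1, 1].

    Each null sample keeps its observed richness, draws that many distinct
    taxa with probability proportional to occupancy across the pool, then
    allocates its observed read total multinomially proportional to the
    pool's relative abundances restricted to the drawn taxa. RC is
    (#{BC_null < BC_obs} + 0.5 * #{BC_null = BC_obs}) / reps, mapped through
    (RC - 0.5) * 2.

    ``pool`` defaults to the table itself (callers doing per-group
    classification pass the group's table). With ``exact`` the null
    distribution is enumerated analytically instead of sampled, which is
    only feasible for very small pools (few taxa, few reads).
    """
    j, k = pair
    pool = pool if pool is not None else table
    counts = table.counts[pool.taxon_ids]
    row_j = counts.loc[j].to_numpy(dtype=float)
    row_k = counts.loc[k].to_numpy(dtype=float)
    if row_j.sum() == 0 or row_k.sum() == 0:
        raise ValueError(f"empty sample in pair ({j}, {k})")
    occupancy = (pool.counts.to_numpy() > 0).sum(axis=0).astype(float)
    if occupancy.sum() == 0:
        raise ValueError("empty pool")
    meta_p = pool.counts.to_numpy().sum(axis=0).astype(float)
    meta_p = meta_p / meta_p.sum()
    occupancy_p = occupancy / occupancy.sum()
    rich_j = int((row_j > 0).sum())
    rich_k = int((row_k > 0).sum())
    n_avail = int((occupancy > 0).sum())
    if max(rich_j, rich_k) > n_avail:
        raise ValueError(
            "sample richness exceeds the number of taxa in the pool"
        )
    obs = _bray(row_j, row_k)
    if exact:
        return _rc_bray_exact(
            obs,
            (rich_j, int(row_j.sum())),
            (rich_k, int(row_k.sum())),
            occupancy_p,
            meta_p,
        )
    rng = np.random.default_rng(seed)
    reads_j = int(row_j.sum())
    reads_k = int(row_k.sum())
    chosen_j = _null_choices(rich_j, occupancy_p, reps, rng)
    chosen_k = _null_choices(rich_k, occupancy_p, reps, rng)
    less = 0.0
    for r in range(reps):
        cj, ck = chosen_j[r], chosen_k[r]
        qj = meta_p[cj]
        qk = meta_p[ck]
        u = rng.multinomial(reads_j, qj / qj.sum()) / reads_j
        v = rng.multinomial(reads_k, qk / qk.sum()) / reads_k
        _, ia, ib = np.intersect1d(
            cj, ck, assume_unique=True, return_indices=True
        )
        bc = 1.0 - np.minimum(u[ia], v[ib]).sum()
        if bc < obs - 1e-12:
            less += 1.0
        elif abs(bc - obs) <= 1e-12:
            less += 0.5
    return float((less / reps - 0.5) * 2.0)


def _subset_probability(subset, weights: np.ndarray) -> float:
    """P(drawing exactly this subset by successive weighted sampling w/o
    replacement), summed over all draw orders."""
    total = 0.0
    for order in itertools.permutations(subset):
        prob = 1.0
        remaining = 1.0
        for t in order:
            prob *= weights[t] / remaining
            remaining -= weights[t]
        total += prob
    return total


def _null_distribution(richness, reads, occupancy_p, meta_p):
    """Exact null distribution over count vectors for one sample."""
    n_taxa = len(occupancy_p)
    support = [i for i in range(n_taxa) if occupancy_p[i] > 0]
    dist: list[tuple[np.ndarray, float]] = []
    for subset in itertools.combinations(support, richness):
        p_subset = _subset_probability(subset, occupancy_p)
        q = meta_p[list(subset)]
        q = q / q.sum()
        for alloc in _compositions(reads, richness):
            pmf = math.factorial(reads)
            for c, qi in zip(alloc, q):
                pmf = pmf * qi**c / math.factorial(c)
            vec = np.zeros(n_taxa)
            vec[list(subset)] = alloc
            dist.append((vec, p_subset * pmf))
    return dist


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


def _rc_bray_exact(obs, spec_j, spec_k, occupancy_p, meta_p) -> float:
    dist_j = _null_distribution(*spec_j, occupancy_p, meta_p)
    dist_k = _null_distribution(*spec_k, occupancy_p, meta_p)
    less = 0.0
    for vec_j, p_j in dist_j:
        if vec_j.sum() == 0:
            continue
        for vec_k, p_k in dist_k:
            if vec_k.sum() == 0:
                continue
            bc = _bray(vec_j, vec_k)
            w = p_j * p_k
            if bc < obs - 1e-12:
                less += w
            elif abs(bc - obs) <= 1e-12:
                less += 0.5 * w
    return float((less - 0.5) * 2.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_process(bnti_value: float, rc_value: float) -> str | None:
    """Five-way ecological-process label from (betaNTI, RC_bray).

    Selection labels depend on betaNTI alone; RC_bray splits the stochastic
    band. An undefined (NaN) betaNTI propagates as None.
    """
    if bnti_value is None or (
        isinstance(bnti_value, float) and math.isnan(bnti_value)
    ):
        return None
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value is None or (isinstance(rc_value, float) and math.isnan(rc_value)):
        return None
    if rc_value >= 0.95:
        return "dispersal_limitation"
    if rc_value <= -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def summarize_processes(pairs: pd.DataFrame, group_by: str = "group") -> pd.DataFrame:
    """Within-group percentage of each process label.

    Pairs with an undefined process (NaN betaNTI) are excluded with a
    logged count; percentages sum to 100 within each group.
    """
    frame = pairs.copy()
    n_na = frame["process"].isna().sum()
    if n_na:
        logger.warning("excluding %d pairs with undefined process", n_na)
        frame = frame.dropna(subset=["process"])
    if group_by not in frame.columns:
        frame[group_by] = "all"
    rows = []
    for label, sub in frame.groupby(group_by, sort=False):
        if len(sub) == 0:
            logger.warning("empty group %r dropped", label)
            continue
        counts = sub["process"].value_counts()
        rec = {group_by: label, "n_pairs": len(sub)}
        for proc in PROCESSES:
            rec[proc] = 100.0 * counts.get(proc, 0) / len(sub)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class AssemblyModel:
    """Pairwise community-assembly inference on an OTU table and phylogeny.

    Parameters
    ----------
    table : OtuTable
        Count table; its ``groups`` labels (if any) define the analysis
        groups. Pairs are formed within groups.
    dist : DataFrame
        Patristic tip-distance matrix covering the table's taxa (see
        `ecoassembly.phylo.patristic_matrix`).
    weighted : bool
        Abundance-weighted betaMNTD (default) or presence/absence.
    pool_by_group : bool
        RC_bray null metacommunity = the pair's group (default) or the full
        table.
    """

    def __init__(
        self,
        table: OtuTable,
        dist: pd.DataFrame,
        weighted: bool = True,
        pool_by_group: bool = True,
    ):
        missing = set(table.taxon_ids) - set(dist.index)
        if missing:
            raise ValueError(
                f"distance matrix missing taxa: {sorted(missing)[:5]}"
            )
        self.table = table
        self.dist = dist.loc[table.taxon_ids, table.taxon_ids]
        self.weighted = weighted
        self.pool_by_group = pool_by_group

    def _pairs(self, scope: str):
        table = self.table
        if table.groups is None or scope == "all":
            yield "all", list(itertools.combinations(table.sample_ids, 2))
            return
        if scope == "within":
            for label, sub in table.groupby():
                yield label, list(itertools.combinations(sub.sample_ids, 2))
        elif scope == "between":
            groups = table.groups
            pairs = [
                (j, k)
                for j, k in itertools.combinations(table.sample_ids, 2)
                if groups[j] != groups[k]
            ]
            yield "between", pairs
        else:
            raise ValueError(f"unknown pair scope: {scope!r}")

    def fit(
        self, reps: int = 999, seed=None, pair_scope: str = "within"
    ) -> "AssemblyResults":
        """Compute betaMNTD, betaNTI, RC_bray and the process label per pair.

        ``pair_scope`` chooses which sample pairs are analysed: "within"
        (default; pairs inside each group), "between" (cross-group pairs
        only) or "all". One shared set of ``reps`` tip shuffles drives all
        pairs' betaNTI nulls (the null is a property of the randomisation,
        not the pair), which keeps the run at O(reps * pairs * S^2) array
        work.
        """
        rng = np.random.default_rng(seed)
        table = self.table
        D = self.dist.to_numpy()
        n_taxa = D.shape[0]
        counts = table.counts[self.dist.index]
        rel = counts.div(counts.sum(axis=1), axis=0)

        bray = beta_matrix(table, "bray")
        jacc = beta_matrix(table, "jaccard")

        # per-sample present-taxon indices and weights
        present: dict[str, np.ndarray] = {}
        weight: dict[str, np.ndarray] = {}
        for sid in table.sample_ids:
            row = counts.loc[sid].to_numpy(dtype=float)
            idx = np.flatnonzero(row)
            present[sid] = idx
            if self.weighted:
                weight[sid] = row[idx] / row.sum()
            else:
                weight[sid] = np.full(len(idx), 1.0 / len(idx))

        group_pairs = list(self._pairs(pair_scope))
        all_pairs = [
            (label, j, k) for label, pairs in group_pairs for j, k in pairs
        ]

        obs = np.array(
            [
                _bmntd_arrays(D, weight[j], weight[k], present[j], present[k])
                for _, j, k in all_pairs
            ]
        )
        null_sum = np.zeros(len(all_pairs))
        null_sumsq = np.zeros(len(all_pairs))
        for _ in range(reps):
            perm = rng.permutation(n_taxa)
            for i, (_, j, k) in enumerate(all_pairs):
                v = _bmntd_arrays(
                    D, weight[j], weight[k], perm[present[j]], perm[present[k]]
                )
                null_sum[i] += v
                null_sumsq[i] += v * v
        mean = null_sum / reps
        var = np.maximum(null_sumsq / reps - mean**2, 0.0)
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            bnti_vals = np.where(sd > 0, (obs - mean) / sd, np.nan)
        n_degenerate = int((sd == 0).sum())
        if n_degenerate:
            warnings.warn(
                f"{n_degenerate} pairs have a degenerate betaNTI null "
                "(zero spread); flagged NaN"
            )

        # RC_bray, pooled per group by default
        pools = {}
        for label, _ in group_pairs:
            if (
                self.pool_by_group
                and table.groups is not None
                and (table.groups == label).any()
            ):
                ids = table.groups.index[table.groups == label]
                pools[label] = table.select_samples(ids)
            else:
                pools[label] = table
        rc_vals = np.empty(len(all_pairs))
        for i, (label, j, k) in enumerate(all_pairs):
            rc_vals[i] = rc_bray(
                table,
                (j, k),
                reps=reps,
                seed=rng.integers(2**31),
                pool=pools[label],
            )

        records = []
        for i, (label, j, k) in enumerate(all_pairs):
            records.append(
                {
                    "group": label,
                    "sample_j": j,
                    "sample_k": k,
                    "bray": bray[j, k],
                    "jaccard": jacc[j, k],
                    "bmntd": obs[i],
                    "bnti": bnti_vals[i],
                    "rc_bray": rc_vals[i],
                    "process": classify_process(bnti_vals[i], rc_vals[i]),
                }
            )
        return AssemblyResults(pd.DataFrame(records), reps=reps)


@dataclass
class AssemblyResults:
    """Per-pair assembly metrics plus process-percentage summaries."""

    pairs: pd.DataFrame
    reps: int

    def process_summary(self) -> pd.DataFrame:
        return summarize_processes(self.pairs, "group")

    def summary(self) -> str:
        lines = [
            "Community assembly (betaNTI / RC_bray null models)",
            f"  pairs: {len(self.pairs)}   randomizations: {self.reps}",
            "",
            self.process_summary().to_string(
                index=False, float_format=lambda v: f"{v:.2f}"
            ),
        ]
        return "\n".join(lines)
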