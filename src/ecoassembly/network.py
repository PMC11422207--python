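"""Co-occurrence networks, topology metrics, and Zi-Pi keystone roles.

The construction mirrors common microbiome practice: restrict to the most
abundant taxa in the analysis group, keep Spearman pairs with |r| above a
hard threshold and raw p below alpha (no multiple-testing correction unless
asked), and read the resulting graph with Gephi-equivalent metrics. Edge
weight is |r| (sign kept as an attribute) because negative weights break
standard modularity; diameter and path length are taken on the largest
connected component, as Gephi does on disconnected graphs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations as _perms

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ecoassembly.containers import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "select_top_taxa",
    "build_network",
    "CooccurrenceNetwork",
    "TopologySummary",
    "topology_summary_from_graph",
    "louvain_modules",
    "zi_pi",
    "abundance_category",
    "core_taxa",
    "spearman_edges",
]

ABUNDANCE_CATEGORIES = ("AAT", "CAT", "ART", "CRT", "MT", "CRAT")


# ---------------------------------------------------------------------------
# taxon selection and correlation
# ---------------------------------------------------------------------------

def select_top_taxa(table: OtuTable, k: int = 300) -> list[str]:
    """The k taxa with the highest total counts; ties broken by id.

    Sorting is by (-total, taxon id), so at a tied boundary the
    lexicographically smaller id is retained.
    """
    if k > table.n_taxa:
        raise ValueError(f"k={k} exceeds {table.n_taxa} taxa")
    totals = table.counts.sum(axis=0)
    order = sorted(totals.index, key=lambda t: (-totals[t], t))
    return order[:k]


@lru_cache(maxsize=8)
def _exact_rho_perms(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1 (cached); feasible for n < 10."""
    return np.array(list(_perms(range(n))))


def _exact_p(rank_x: np.ndarray, rank_y: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p for Spearman r (ties handled by
    permuting one midrank vector over all n! orders)."""
    P = _exact_rho_perms(len(rank_x))
    xs = rank_x[P]  # all permuted rank vectors
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = rank_y - rank_y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore"):
        rs = (xc @ yc) / denom
    return float((np.abs(rs) >= abs(r_obs) - 1e-12).mean())


def spearman_edges(
    mat: np.ndarray, taxon_ids: list[str], r_threshold: float, alpha: float
) -> pd.DataFrame:
    """All taxon pairs passing |r| > r_threshold and p < alpha.

    p-values use the t approximation on n-2 df for n >= 10 samples and the
    exact permutation distribution below that. Constant taxa are excluded
    with a warning (their correlation is undefined).
    """
    n_samples, n_taxa = mat.shape
    const = mat.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"excluding {int(const.sum())} constant taxa from correlation"
        )
    keep = ~const
    mat = mat[:, keep]
    ids = [t for t, k in zip(taxon_ids, keep) if k]
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    rc = ranks - ranks.mean(axis=0)
    norms = np.sqrt((rc**2).sum(axis=0))
    R = (rc.T @ rc) / np.outer(norms, norms)
    np.clip(R, -1.0, 1.0, out=R)
    iu, ju = np.triu_indices(len(ids), k=1)
    r = R[iu, ju]
    if n_samples >= 10:
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n_samples - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n_samples - 2)
    else:
        if n_samples < 4:
            raise ValueError("need >= 4 samples for edge significance")
        p = np.array(
            [
                _exact_p(ranks[:, i], ranks[:, j], rv)
                for i, j, rv in zip(iu, ju, r)
            ]
        )
    mask = (np.abs(r) > r_threshold) & (p < alpha)
    return pd.DataFrame(
        {
            "u": [ids[i] for i in iu[mask]],
            "v": [ids[j] for j in ju[mask]],
            "r": r[mask],
            "p": p[mask],
            "sign": np.sign(r[mask]).astype(int),
        }
    )


def build_network(
    table: OtuTable,
    r_threshold: float = 0.9,
    alpha: float = 0.05,
    top_k: int | None = None,
    fdr: bool = False,
) -> "CooccurrenceNetwork":
    """Thresholded Spearman co-occurrence network for one table/group.

    Nodes are the taxa incident to at least one retained edge, annotated
    with mean relative abundance (and phylum when taxonomy is present).
    ``fdr`` applies Benjamini-Hochberg to the p-values before thresholding
    (off by default: the conventional filter is raw p < alpha).
    """
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples to build a network")
    sub = table if top_k is None else table.select_taxa(select_top_taxa(table, top_k))
    edges = spearman_edges(
        sub.counts.to_numpy(dtype=float), sub.taxon_ids, r_threshold, alpha
    )
    if fdr and len(edges):
        from statsmodels.stats.multitest import multipletests  # lazy: optional path

        ok = multipletests(edges["p"], alpha=alpha, method="fdr_bh")[0]
        edges = edges[ok].reset_index(drop=True)
    g = nx.Graph()
    rel = sub.relative_abundance().mean(axis=0)
    for _, row in edges.iterrows():
        g.add_edge(
            row["u"],
            row["v"],
            r=float(row["r"]),
            p=float(row["p"]),
            sign=int(row["sign"]),
            weight=abs(float(row["r"])),
        )
    for node in g.nodes:
        g.nodes[node]["mean_relative_abundance"] = float(rel[node])
        if sub.taxonomy is not None:
            parts = [s.strip() for s in str(sub.taxonomy[node]).split(";")]
            g.nodes[node]["phylum"] = parts[1] if len(parts) > 1 else parts[0]
    return CooccurrenceNetwork(graph=g, table=sub, edges=edges)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float
    average_degree: float
    average_weighted_degree: float
    diameter: float
    graph_density: float
    modularity: float
    average_clustering_coefficient: float
    average_path_length: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def louvain_modules(
    graph: nx.Graph, seed: int = 0, restarts: int = 10, resolution: float = 1.0
) -> dict:
    """Louvain partition (positive |r| weights), best of ``restarts`` runs.

    Louvain is stochastic and Gephi's exact partition is not reproducible;
    running several seeded restarts and keeping the max-modularity
    partition makes the value stable enough to compare as a property.
    """
    best, best_q = None, -np.inf
    for i in range(restarts):
        parts = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed + i
        )
        q = nx.community.modularity(graph, parts, weight="weight")
        if q > best_q:
            best, best_q = parts, q
    return {node: m for m, part in enumerate(best) for node in part}


def topology_summary_from_graph(graph: nx.Graph, seed: int = 0) -> TopologySummary:
    """Gephi-equivalent topology metrics of a signed, |r|-weighted graph."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in graph.edges(data=True)]
    n_pos = int(sum(1 for s in signs if s > 0))
    n_neg = e - n_pos
    wdeg = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    lcc = graph.subgraph(max(nx.connected_components(graph), key=len))
    if lcc.number_of_nodes() > 1:
        diameter = float(nx.diameter(lcc))
        apl = float(nx.average_shortest_path_length(lcc))
    else:
        diameter, apl = 0.0, 0.0
    modules = louvain_modules(graph, seed=seed)
    parts = {}
    for node, m in modules.items():
        parts.setdefault(m, set()).add(node)
    q = nx.community.modularity(graph, parts.values(), weight="weight")
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        n_positive=n_pos,
        n_negative=n_neg,
        pct_positive=100.0 * n_pos / e if e else 0.0,
        pct_negative=100.0 * n_neg / e if e else 0.0,
        average_degree=2.0 * e / n,
        average_weighted_degree=2.0 * wdeg / n,
        diameter=diameter,
        graph_density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        modularity=float(q),
        average_clustering_coefficient=float(nx.average_clustering(graph)),
        average_path_length=apl,
    )


# ---------------------------------------------------------------------------
# Zi-Pi roles and abundance categories
# ---------------------------------------------------------------------------

def zi_pi(graph: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Zi standardises a node's link count into its own module against that
    module's distribution (sd 0 -> Zi = 0); Pi = 1 - sum_t (k_t/k)^2 over
    modules t. Thresholds Zi 2.5 and Pi 0.62 split peripheral / module hub
    / network hub / connector, with the boundary itself falling to the
    peripheral/connector side; any non-peripheral node is a keystone.
    """
    missing = set(graph.nodes) - set(modules)
    if missing:
        raise ValueError(f"modules missing for nodes: {sorted(missing)[:5]}")
    within = {}
    permod = {}
    for node in graph.nodes:
        counts: dict = {}
        for nb in graph.neighbors(node):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        permod[node] = counts
        within[node] = counts.get(modules[node], 0)
    by_module: dict = {}
    for node in graph.nodes:
        by_module.setdefault(modules[node], []).append(within[node])
    stats_ = {
        m: (np.mean(v), np.std(v)) for m, v in by_module.items()
    }
    records = []
    for node in graph.nodes:
        k = graph.degree(node)
        mean, sd = stats_[modules[node]]
        if k == 0:
            zi = 0.0  # isolated nodes are defined as Zi = 0
        else:
            zi = (within[node] - mean) / sd if sd > 0 else 0.0
        if k > 0:
            pi = 1.0 - sum((c / k) ** 2 for c in permod[node].values())
        else:
            pi = 0.0
        if zi > 2.5 and pi > 0.62:
            role = "network_hub"
        elif zi > 2.5:
            role = "module_hub"
        elif pi > 0.62:
            role = "connector"
        else:
            role = "peripheral"
        records.append(
            {
                "node": node,
                "module": modules[node],
                "Zi": zi,
                "Pi": pi,
                "role": role,
                "keystone": role != "peripheral",
            }
        )
    return pd.DataFrame(records).set_index("node")


def abundance_category(table: OtuTable, taxon: str) -> str:
    """Six-way abundance category of one taxon across the table's samples.

    AAT >= 1% everywhere; ART < 0.01% everywhere; MT in [0.01%, 1%)
    everywhere; CAT >= 0.01% everywhere and >= 1% somewhere; CRAT spans
    < 0.01% to >= 1%; CRT < 0.01% somewhere, never >= 1%. Checked in the
    order AAT, ART, MT, CAT, CRAT, CRT so the categories are exhaustive
    and mutually exclusive.
    """
    if taxon not in table.counts.columns:
        raise KeyError(taxon)
    rel = table.relative_abundance()[taxon].to_numpy()
    abundant, rare = 0.01, 0.0001
    if np.all(rel >= abundant):
        return "AAT"
    if np.all(rel < rare):
        return "ART"
    if np.all((rel >= rare) & (rel < abundant)):
        return "MT"
    if np.all(rel >= rare):  # some >= 1% (else MT above)
        return "CAT"
    if np.any(rel >= abundant):  # and some < 0.01%
        return "CRAT"
    return "CRT"


def core_taxa(tables_by_group: dict[str, OtuTable]) -> dict:
    """Venn regions of taxon presence across >= 2 groups.

    Presence = nonzero count in at least one sample of the group. Returns
    the core (intersection), per-group exclusives, and every Venn region
    with counts and percentages of the union.
    """
    if len(tables_by_group) < 2:
        raise ValueError("need >= 2 groups")
    present = {
        g: set(t.counts.columns[(t.counts > 0).any(axis=0)])
        for g, t in tables_by_group.items()
    }
    groups = list(present)
    union = set().union(*present.values())
    core = set.intersection(*present.values())
    regions = {}
    for mask in range(1, 2 ** len(groups)):
        inside = [g for i, g in enumerate(groups) if mask >> i & 1]
        outside = [g for g in groups if g not in inside]
        region = set.intersection(*(present[g] for g in inside))
        for g in outside:
            region -= present[g]
        key = "&".join(inside)
        regions[key] = {
            "taxa": region,
            "count": len(region),
            "pct_of_union": 100.0 * len(region) / len(union) if union else 0.0,
        }
    return {
        "union": union,
        "core": core,
        "core_pct_of_union": 100.0 * len(core) / len(union) if union else 0.0,
        "exclusive": {
            g: present[g] - set().union(*(present[h] for h in groups if h != g))
            for g in groups
        },
        "regions": regions,
    }


# ---------------------------------------------------------------------------
# network object
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """A thresholded correlation graph plus its source table and edge list."""

    graph: nx.Graph
    table: OtuTable | None = None
    edges: pd.DataFrame | None = None

    def __post_init__(self):
        degs = dict(self.graph.degree())
        assert sum(degs.values()) == 2 * self.graph.number_of_edges()

    def topology_summary(self, seed: int = 0) -> TopologySummary:
        return topology_summary_from_graph(self.graph, seed=seed)

    def node_roles(self, seed: int = 0) -> pd.DataFrame:
        modules = louvain_modules(self.graph, seed=seed)
        roles = zi_pi(self.graph, modules)
        if self.table is not None:
            roles["abundance_category"] = [
                abundance_category(self.table, t) for t in roles.index
            ]
        return roles

    def summary(self, seed: int = 0) -> str:
        ts = self.topology_summary(seed=seed)
        roles = self.node_roles(seed=seed)
        n_key = int(roles["keystone"].sum())
        return "\n".join(
            [
                "Co-occurrence network",
                f"  nodes: {ts.n_nodes}   edges: {ts.n_edges} "
                f"({ts.pct_positive:.2f}% positive)",
                f"  average degree: {ts.average_degree:.3f}   density: "
                f"{ts.graph_density:.3f}   modularity: {ts.modularity:.3f}",
                f"  keystone nodes (module hubs + connectors + network "
                f"hubs): {n_key}",
            ]
        )
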