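"""Synthetic communities, phylogenies and networks with known ground truth.

Three generators mirror the data-generating processes the downstream
inference is supposed to detect:

* `simulate_neutral` — local communities assembled from a metacommunity by
  drift plus immigration. Marginally, taxon i's local relative abundance is
  Beta(N*m*p_i, N*m*(1-p_i)) — the stationary approximation of neutral drift
  with immigration rate m at community size N — and reads are a multinomial
  draw of N. `forward_neutral_sample` is a deliberately slow Moran-process
  forward simulator kept as the independent cross-check of that
  approximation.
* `simulate_selection` — taxon fitness depends on the squared mismatch
  between a phylogenetically conserved trait (Brownian motion on the tree)
  and a per-sample environment, with selection strength w. w = 0 collapses
  to the neutral lottery at m = 1.
* `planted_partition_graph` — modular graphs with designated hub and
  connector nodes for Zi-Pi role recovery.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from ecoassembly.containers import OtuTable, SampleMetadata

__all__ = [
    "simulate_tree",
    "lognormal_metacommunity",
    "NeutralScenario",
    "simulate_neutral",
    "forward_neutral_sample",
    "SelectionScenario",
    "brownian_traits",
    "simulate_selection",
    "PlantedNetwork",
    "planted_partition_graph",
]


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed=None, birth_rate: float = 1.0) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times.

    Tips are labelled OTU_1..OTU_n. The tree is fully bifurcating (n-1
    internal nodes including the root) and every tip is equidistant from the
    root.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    start = {id(root): 0.0}
    # root splits at t=0 into two lineages
    active = []
    t = 0.0
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        start[id(child)] = t
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node.length = t - start[id(node)]
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            start[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.length = t - start[id(node)]
    # deterministic tip labels in traversal order
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU_{i}"
    return root


def lognormal_metacommunity(
    n_taxa: int, sigma: float = 1.5, seed=None
) -> np.ndarray:
    """Lognormal rank-abundance metacommunity, normalised to sum to 1.

    sigma = 1.5 gives the realistic skew of soil communities without the
    heavy tails that destabilise multinomial sampling.
    """
    rng = np.random.default_rng(seed)
    ab = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    return ab / ab.sum()


# ---------------------------------------------------------------------------
# neutral assembly
# ---------------------------------------------------------------------------

@dataclass
class NeutralScenario:
    """Parameters of a neutral local-community ensemble.

    m_true is the migration (immigration) rate in (0, 1]; reads is the
    sequencing depth N per sample, which doubles as the community size in
    the Beta stationary approximation.
    """

    n_taxa: int = 500
    n_samples: int = 42
    m_true: float = 0.1
    reads: int = 30_892
    sigma: float = 1.5
    seed: int | None = None
    metacommunity: np.ndarray | None = None
    group: str = "all"

    def __post_init__(self):
        if not (0 < self.m_true <= 1):
            raise ValueError("m_true must be in (0, 1]")
        if self.metacommunity is not None:
            p = np.asarray(self.metacommunity, dtype=float)
            if p.min() < 0 or not np.isclose(p.sum(), 1.0):
                raise ValueError("metacommunity must be a probability vector")
            self.metacommunity = p
            self.n_taxa = len(p)


def _neutral_rel_abundance(
    p: np.ndarray, Nm: float, rng: np.random.Generator
) -> np.ndarray:
    """One sample's relative abundances under the Beta marginal model."""
    a = Nm * p
    b = Nm * (1.0 - p)
    x = np.zeros_like(p)
    pos = (p > 0) & (p < 1)
    x[pos] = rng.beta(a[pos], b[pos])
    x[p >= 1] = 1.0
    s = x.sum()
    if s == 0:  # pathological tiny-Nm draw; fall back to the metacommunity
        return p.copy()
    return x / s


def simulate_neutral(
    scenario: NeutralScenario,
) -> tuple[OtuTable, SampleMetadata]:
    """Draw an OTU table from the neutral drift + immigration model.

    Each sample draws per-taxon relative abundances from the Beta marginal
    (normalised across taxa), then reads by a multinomial of size
    ``scenario.reads``. The ground-truth m is recorded in the metadata.
    """
    rng = np.random.default_rng(scenario.seed)
    p = scenario.metacommunity
    if p is None:
        p = lognormal_metacommunity(scenario.n_taxa, scenario.sigma, rng)
    Nm = scenario.reads * scenario.m_true
    counts = np.empty((scenario.n_samples, scenario.n_taxa), dtype=np.int64)
    for s in range(scenario.n_samples):
        x = _neutral_rel_abundance(p, Nm, rng)
        counts[s] = rng.multinomial(scenario.reads, x)
    sample_ids = [f"S{i + 1}" for i in range(scenario.n_samples)]
    taxon_ids = [f"OTU_{j + 1}" for j in range(scenario.n_taxa)]
    groups = pd.Series(scenario.group, index=sample_ids)
    table = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        groups=groups,
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"group": scenario.group, "m_true": scenario.m_true},
            index=sample_ids,
        )
    )
    return table, meta


def forward_neutral_sample(
    p: np.ndarray,
    m: float,
    community_size: int,
    n_steps: int | None = None,
    seed=None,
) -> np.ndarray:
    """Forward Moran simulation of neutral drift with immigration (slow oracle).

    A local community of ``community_size`` individuals: at each step one
    random individual dies and is replaced from the metacommunity with
    probability m, else by copying a random survivor. Returns the relative
    abundance vector after ``n_steps`` (default 20 turnovers of the
    community). Used only to cross-check the Beta marginal approximation.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    J = community_size
    if n_steps is None:
        n_steps = 20 * J
    community = rng.choice(len(p), size=J, p=p)
    for _ in range(n_steps):
        die = rng.integers(J)
        if rng.random() < m:
            community[die] = rng.choice(len(p), p=p)
        else:
            survivor = rng.integers(J - 1)
            if survivor >= die:
                survivor += 1
            community[die] = community[survivor]
    return np.bincount(community, minlength=len(p)) / J


# ---------------------------------------------------------------------------
# selection-structured assembly
# ---------------------------------------------------------------------------

def brownian_traits(
    tree: TreeNode, rate: float = 1.0, seed=None, standardize: bool = True
) -> pd.Series:
    """Brownian-motion trait evolution on the tree (variance = rate * time).

    With ``standardize`` the tip traits are z-scored so environment values
    are expressed in trait standard deviations regardless of tree height.
    """
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        values[id(node)] = parent_val + rng.normal(
            0.0, np.sqrt(rate * (node.length or 0.0))
        )
    tips = list(tree.tips())
    traits = pd.Series(
        [values[id(t)] for t in tips], index=[t.name for t in tips]
    )
    if standardize:
        traits = (traits - traits.mean()) / traits.std(ddof=0)
    return traits


@dataclass
class SelectionScenario:
    """Selection-structured communities on a simulated phylogeny.

    Sampling weight of taxon i in sample s is
    x_is * exp(-w * (trait_i - e_s)^2), where x_is is the sample's neutral
    lottery draw: the metacommunity p itself at drift_m = 1 (so w = 0
    reduces exactly to the neutral lottery at m = 1), or a Beta-marginal
    drift draw at drift_m < 1, which adds the taxonomic turnover between
    samples that selection alone does not create.
    """

    n_taxa: int = 200
    w: float = 5.0
    sigma2: float = 1.0
    reads: int = 2000
    sigma: float = 1.5
    drift_m: float = 1.0
    seed: int | None = None
    tree: TreeNode | None = field(default=None, repr=False)
    metacommunity: np.ndarray | None = None

    def __post_init__(self):
        if self.w < 0:
            raise ValueError("selection strength w must be >= 0")


def simulate_selection(
    scenario: SelectionScenario,
    env_values,
    groups=None,
) -> tuple[OtuTable, SampleMetadata, TreeNode, pd.Series]:
    """Draw selection-structured communities along an environmental gradient.

    Parameters
    ----------
    env_values : sequence of float
        Per-sample environment e_s, in trait standard deviations. Equal
        values across samples give the homogeneous-selection regime;
        strongly contrasting values the variable-selection regime.
    groups : sequence of str, optional
        Per-sample group labels (default: the stringified environment).

    Returns the table, metadata, the tree used, and the tip traits.
    """
    env = np.asarray(env_values, dtype=float)
    n_samples = len(env)
    rng = np.random.default_rng(scenario.seed)
    tree = scenario.tree
    if tree is None:
        tree = simulate_tree(scenario.n_taxa, seed=rng.integers(2**31))
    taxon_ids = [t.name for t in tree.tips()]
    n_taxa = len(taxon_ids)
    p = scenario.metacommunity
    if p is None:
        p = lognormal_metacommunity(n_taxa, scenario.sigma, rng)
    traits = brownian_traits(tree, rate=scenario.sigma2, seed=rng.integers(2**31))
    traits = traits.reindex(taxon_ids)
    tr = traits.to_numpy()
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        if scenario.drift_m < 1:
            x = _neutral_rel_abundance(
                p, scenario.reads * scenario.drift_m, rng
            )
        else:
            x = p
        weight = x * np.exp(-scenario.w * (tr - env[s]) ** 2)
        total = weight.sum()
        if total == 0:
            raise ValueError(
                "all sampling weights underflowed; reduce w or the "
                "environment range"
            )
        counts[s] = rng.multinomial(scenario.reads, weight / total)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    if groups is None:
        groups = [f"env={e:g}" for e in env]
    groups = pd.Series(list(groups), index=sample_ids)
    table = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        groups=groups,
    )
    meta = SampleMetadata(
        pd.DataFrame({"group": groups, "env": env}, index=sample_ids)
    )
    return table, meta, tree, traits


# ---------------------------------------------------------------------------
# planted interaction networks
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """A planted-partition graph with optional designated hubs/connectors.

    ``hubs`` lists nodes to be wired to every other node of their own module
    (module-hub degree pattern); ``connectors`` lists nodes whose edges are
    replaced by ``connector_links`` links into every module, spreading
    their degree evenly across modules (high among-module connectivity).
    """

    module_sizes: tuple = (30, 30, 30)
    p_in: float = 0.9
    p_out: float = 0.01
    hubs: tuple = ()
    connectors: tuple = ()
    connector_links: int = 8
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need p_in > p_out within [0, 1]")


def planted_partition_graph(
    spec: PlantedNetwork,
) -> tuple[nx.Graph, dict[int, int]]:
    """Simple undirected planted-partition graph plus true module labels."""
    rng = np.random.default_rng(spec.seed)
    labels: dict[int, int] = {}
    node = 0
    modules: list[list[int]] = []
    for mod, size in enumerate(spec.module_sizes):
        members = list(range(node, node + size))
        modules.append(members)
        for v in members:
            labels[v] = mod
        node += size
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = node
    for u in range(n):
        for v in range(u + 1, n):
            p = spec.p_in if labels[u] == labels[v] else spec.p_out
            if p > 0 and rng.random() < p:
                g.add_edge(u, v)
    for h in spec.hubs:
        for v in modules[labels[h]]:
            if v != h:
                g.add_edge(h, v)
    for c in spec.connectors:
        g.remove_edges_from(list(g.edges(c)))
        for mod, members in enumerate(modules):
            candidates = [v for v in members if v != c]
            k = min(spec.connector_links, len(candidates))
            for v in rng.choice(candidates, size=k, replace=False):
                g.add_edge(c, int(v))
    return g, labels
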