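"""Structural decomposition of an adoption process.

Given a substrate graph and an event log of (node, adoption time) records —
simulated or empirical — this module reconstructs the objects that
characterise how adoption spread:

* the **adoption network**: substrate edges between adopters whose adoption
  times differ (same-time links are excluded because instantaneous group
  adoptions carry no evidence of social influence);
* the observational **classification** of each adopter by the number
  ``Phi_k`` of neighbours that adopted strictly earlier: innovator
  (``Phi_k = 0``), vulnerable (``Phi_k = 1``), stable (``Phi_k > 1``);
* the **stable subnetwork** induced on stable adopters;
* the **vulnerable forest**: each vulnerable adopter hangs off its unique
  strictly-earlier adopting neighbour; chains of vulnerable nodes terminate
  at a non-vulnerable root (innovator or stable adopter);
* connected-component statistics and the maximum relative growth rate (RGR)
  of cumulative adoption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dynamics_mc import gather_neighbors

__all__ = [
    "Subgraph",
    "ComponentStats",
    "classify",
    "build_adoption_network",
    "stable_subnetwork",
    "vulnerable_forest",
    "component_stats",
    "innovator_tree_correlation",
    "max_relative_growth_rate",
]

logger = logging.getLogger(__name__)

CLASS_NAMES = np.array(["innovator", "vulnerable", "stable"])


def _as_substrate(substrate):
    """Accept a Population/Substrate-like object or a networkx graph."""
    if hasattr(substrate, "indptr") and hasattr(substrate, "indices"):
        return substrate
    import networkx as nx

    if isinstance(substrate, nx.Graph):
        from .population import Population

        n = substrate.number_of_nodes()
        mapping = {v: i for i, v in enumerate(sorted(substrate.nodes()))}
        if any(mapping[v] != v for v in substrate.nodes()):
            raise ValueError("networkx substrate must have integer nodes 0..n-1")
        edges = np.array([(u, v) for u, v in substrate.edges() if u != v], dtype=np.int64).reshape(-1, 2)
        return Population.from_edges(n, edges)
    raise TypeError("substrate must be a Population-like object or networkx Graph")


def _times_array(sub, log: pd.DataFrame) -> np.ndarray:
    """Adoption time per node (0 = never adopted), validated against ``sub``."""
    node = np.asarray(log["node"], dtype=np.int64)
    t = np.asarray(log["t"], dtype=np.int64)
    if node.size and (node.min() < 0 or node.max() >= sub.n):
        bad = node[(node < 0) | (node >= sub.n)][0]
        raise ValueError(f"adopter {bad} is absent from the substrate")
    if len(np.unique(node)) != len(node):
        raise ValueError("duplicate adoption record in event log")
    if node.size and t.min() < 1:
        raise ValueError("adoption times must be >= 1")
    t_adopt = np.zeros(sub.n, dtype=np.int64)
    t_adopt[node] = t
    return t_adopt


@dataclass
class Subgraph:
    """A node-induced subgraph of the substrate, kept as flat arrays."""

    nodes: np.ndarray
    edges: np.ndarray  # (E, 2), endpoints are substrate node ids

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes.tolist())
        g.add_edges_from(map(tuple, self.edges))
        return g


def classify(substrate, log: pd.DataFrame) -> pd.DataFrame:
    """Observational class of every adopter in the log.

    ``Phi_k`` counts neighbours whose adoption time is *strictly* smaller
    than the ego's; two neighbours adopting at the same time therefore
    exclude each other. Returns a DataFrame with columns
    ``node, t, phi_k, cls``.
    """
    sub = _as_substrate(substrate)
    t_adopt = _times_array(sub, log)
    adopters = np.asarray(log["node"], dtype=np.int64)
    if adopters.size == 0:
        return pd.DataFrame(columns=["node", "t", "phi_k", "cls"])

    nbrs = gather_neighbors(sub.indptr, sub.indices, adopters)
    counts = (sub.indptr[adopters + 1] - sub.indptr[adopters]).astype(np.int64)
    ego_t = np.repeat(t_adopt[adopters], counts)
    earlier = (t_adopt[nbrs] > 0) & (t_adopt[nbrs] < ego_t)
    # segment sums over the per-adopter neighbour blocks
    seg = np.repeat(np.arange(len(adopters)), counts)
    phi = np.bincount(seg[earlier], minlength=len(adopters)).astype(np.int64)

    cls = CLASS_NAMES[np.minimum(phi, 2)]
    return pd.DataFrame({"node": adopters, "t": t_adopt[adopters], "phi_k": phi, "cls": cls})


def _adopter_edges(sub, t_adopt: np.ndarray, node_mask: np.ndarray) -> np.ndarray:
    """Substrate edges whose endpoints are both selected and differ in time."""
    e = sub.edges
    if e.size == 0:
        return e.reshape(-1, 2)
    keep = node_mask[e[:, 0]] & node_mask[e[:, 1]] & (t_adopt[e[:, 0]] != t_adopt[e[:, 1]])
    return e[keep]


def build_adoption_network(substrate, log: pd.DataFrame, t: int | None = None) -> Subgraph:
    """Adoption network at time ``t`` (default: end of the log).

    Nodes are adopters with adoption time <= t; edges are substrate edges
    between adopters with *distinct* adoption times.
    """
    sub = _as_substrate(substrate)
    t_adopt = _times_array(sub, log)
    if t is None:
        t = int(t_adopt.max()) if t_adopt.any() else 0
    mask = (t_adopt > 0) & (t_adopt <= t)
    return Subgraph(nodes=np.flatnonzero(mask), edges=_adopter_edges(sub, t_adopt, mask))


def stable_subnetwork(substrate, log: pd.DataFrame, t: int | None = None) -> Subgraph:
    """Induced subgraph on stable adopters (same-time edges excluded)."""
    sub = _as_substrate(substrate)
    cls = classify(sub, log)
    t_adopt = _times_array(sub, log)
    if t is None:
        t = int(t_adopt.max()) if t_adopt.any() else 0
    stable = cls.loc[(cls["cls"] == "stable") & (cls["t"] <= t), "node"].to_numpy()
    mask = np.zeros(sub.n, dtype=bool)
    mask[stable] = True
    return Subgraph(nodes=stable, edges=_adopter_edges(sub, t_adopt, mask))


def vulnerable_forest(substrate, log: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose vulnerable adopters into parent-linked trees.

    Every vulnerable adopter is linked to its parent: the earliest
    strictly-earlier adopting neighbour (ties broken by smallest node id;
    for a true vulnerable node the parent is its unique earlier neighbour).
    Parent chains through vulnerable nodes end at a non-vulnerable *root*
    (innovator or stable adopter). A vulnerable node with no strictly
    earlier neighbour — possible only under same-time collisions — is an
    orphan: excluded and counted in the log.

    Returns
    -------
    (trees, members)
        ``trees``: one row per tree with columns ``root, root_cls,
        root_degree, s_v`` (number of vulnerable members) and ``depth``
        (max hops from the root; a single member gives depth 1).
        ``members``: per vulnerable node its ``root`` and ``depth``
        (orphans carry root -1).
    """
    sub = _as_substrate(substrate)
    cls = classify(sub, log)
    t_adopt = _times_array(sub, log)
    vuln = cls.loc[cls["cls"] == "vulnerable", "node"].to_numpy()
    is_vuln = np.zeros(sub.n, dtype=bool)
    is_vuln[vuln] = True
    cls_by_node = pd.Series(cls["cls"].to_numpy(), index=cls["node"].to_numpy())

    parent = np.full(sub.n, -1, dtype=np.int64)
    orphans = 0
    for v in vuln:
        nb = sub.indices[sub.indptr[v] : sub.indptr[v + 1]]
        tn = t_adopt[nb]
        earlier = nb[(tn > 0) & (tn < t_adopt[v])]
        if earlier.size == 0:
            orphans += 1
            continue
        te = t_adopt[earlier]
        best = earlier[te == te.min()]
        parent[v] = best.min()  # earliest adoption time, then smallest id
    if orphans:
        logger.info("vulnerable forest: %d orphan node(s) excluded (same-time collisions)", orphans)

    # resolve roots/depths in adoption-time order: a parent always adopted
    # strictly earlier, so it is already resolved when its child is visited
    root = np.full(sub.n, -1, dtype=np.int64)
    depth = np.zeros(sub.n, dtype=np.int64)
    order = vuln[np.argsort(t_adopt[vuln], kind="stable")]
    for v in order:
        p = parent[v]
        if p < 0:
            continue
        if is_vuln[p]:
            if root[p] < 0:  # parent was an orphan: propagate exclusion
                continue
            root[v] = root[p]
            depth[v] = depth[p] + 1
        else:
            root[v] = p
            depth[v] = 1

    members = pd.DataFrame(
        {"node": vuln, "root": root[vuln], "depth": depth[vuln]}
    )
    placed = members[members["root"] >= 0]
    if len(placed):
        grp = placed.groupby("root")
        trees = pd.DataFrame(
            {
                "root": grp.size().index.to_numpy(),
                "s_v": grp.size().to_numpy(),
                "depth": grp["depth"].max().to_numpy(),
            }
        )
        trees["root_cls"] = cls_by_node.reindex(trees["root"]).fillna("missing").to_numpy()
        trees["root_degree"] = sub.degree[trees["root"].to_numpy()]
    else:
        trees = pd.DataFrame(columns=["root", "s_v", "depth", "root_cls", "root_degree"])
    return trees, members


@dataclass
class ComponentStats:
    """Connected-component statistics of a (sub)graph."""

    sizes: np.ndarray = field(repr=False)
    lc: int
    lc2: int
    n_nodes: int
    n_total: int  # substrate size used for relative sizes

    @property
    def rel_lc(self) -> float:
        """Largest component relative to substrate size."""
        return self.lc / self.n_total if self.n_total else 0.0

    @property
    def rel_lc_nodes(self) -> float:
        """Largest component relative to the subgraph's own node count."""
        return self.lc / self.n_nodes if self.n_nodes else 0.0

    def size_distribution(self) -> pd.DataFrame:
        s, c = np.unique(self.sizes, return_counts=True)
        return pd.DataFrame({"s": s, "count": c})


def component_stats(graph: Subgraph, n_total: int | None = None) -> ComponentStats:
    """Exact connected components via sparse graph traversal.

    Isolated nodes of the subgraph count as components of size one.
    ``n_total`` fixes the denominator for relative sizes (defaults to the
    subgraph's node count).
    """
    if isinstance(graph, Subgraph):
        nodes, edges = graph.nodes, graph.edges
    else:  # networkx graph
        nodes = np.asarray(sorted(graph.nodes()), dtype=np.int64)
        edges = np.asarray([e for e in graph.edges()], dtype=np.int64).reshape(-1, 2)
    n = len(nodes)
    if n == 0:
        return ComponentStats(sizes=np.empty(0, dtype=np.int64), lc=0, lc2=0, n_nodes=0, n_total=n_total or 0)
    remap = {int(v): i for i, v in enumerate(nodes)}
    if len(edges):
        e0 = np.array([remap[int(u)] for u in edges[:, 0]])
        e1 = np.array([remap[int(v)] for v in edges[:, 1]])
        adj = csr_matrix((np.ones(len(e0)), (e0, e1)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    sizes = np.bincount(labels)
    order = np.sort(sizes)[::-1]
    lc = int(order[0])
    lc2 = int(order[1]) if len(order) > 1 else 0
    return ComponentStats(sizes=sizes, lc=lc, lc2=lc2, n_nodes=n, n_total=n_total or n)


def innovator_tree_correlation(trees: pd.DataFrame) -> pd.DataFrame:
    """Mean vulnerable-tree size by innovator-root degree, ``<s_v>(k)``.

    Only trees rooted at innovators are used (trees hanging off stable
    adopters are excluded). Returns columns ``k, mean_s_v, n_trees``.
    """
    inn = trees[trees["root_cls"] == "innovator"]
    if len(inn) == 0:
        return pd.DataFrame(columns=["k", "mean_s_v", "n_trees"])
    grp = inn.groupby("root_degree")["s_v"]
    return pd.DataFrame(
        {"k": grp.mean().index.to_numpy(), "mean_s_v": grp.mean().to_numpy(), "n_trees": grp.size().to_numpy()}
    )


def max_relative_growth_rate(log: pd.DataFrame, months_per_year: int = 12) -> float:
    """Maximum yearly adoption count over the final cumulative adoptions.

    Event times are months; calendar years are consecutive blocks of
    ``months_per_year`` iterations starting at t = 1. The RGR lies in
    (0, 1]: 1 for an instantaneous cascade (all adoptions within one year),
    1/Y for adoption spread uniformly over Y years.
    """
    if len(log) == 0:
        raise ValueError("RGR undefined: event log contains no adoptions")
    t = np.asarray(log["t"], dtype=np.int64)
    years = (t - 1) // months_per_year
    counts = np.bincount(years)
    return float(counts.max() / len(t))
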