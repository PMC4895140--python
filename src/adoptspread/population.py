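"""Static synthetic substrate: configuration-model graph plus node marks.

A node carries the property vector ``(k, c)``: its degree ``k`` and a type
``c`` encoding its behaviour — ``c = 0`` for *immune* nodes (a fraction ``r``
of the population that never adopts) and ``c >= 1`` for susceptible nodes
with fractional threshold ``phi_c``. Degrees, thresholds and immunity are
mutually independent.

The wiring is the standard configuration model: stubs proportional to the
drawn degree sequence are matched uniformly at random, and the resulting
self-loops and multi-edges are erased (simple-graph output). At the network
sizes used here the erasure loss is a fraction of a percent of the edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distributions import DegreeModel, ThresholdModel

__all__ = [
    "Population",
    "TypeScheme",
    "build_population",
    "discretise_types",
    "degree_classes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TypeScheme:
    """Discretisation of the threshold law into M types for the AME.

    ``phi_c[j]`` is the threshold of type ``j + 1`` (type 0 is reserved for
    immune nodes) and ``p_c[j]`` its probability among non-immune nodes.
    """

    phi_c: np.ndarray
    p_c: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi_c, dtype=float)
        p = np.asarray(self.p_c, dtype=float)
        if phi.ndim != 1 or p.shape != phi.shape:
            raise ValueError("phi_c and p_c must be 1-d arrays of equal length")
        if np.any(phi <= 0) or np.any(phi > 1):
            raise ValueError("type thresholds must lie in (0, 1]")
        if np.any(np.diff(phi) <= 0):
            raise ValueError("type thresholds must be strictly increasing")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("type probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "phi_c", phi)
        object.__setattr__(self, "p_c", p)

    @property
    def n_types(self) -> int:
        return len(self.phi_c)


def discretise_types(thr: ThresholdModel, m: int) -> TypeScheme:
    """Quantile-midpoint discretisation of the threshold law into M types.

    Type ``j + 1`` sits at the ``(j + 1/2)/M`` quantile of the truncated law
    and carries mass ``1/M``. For M = 1 this is the median with mass one.
    """
    if m < 1:
        raise ValueError("number of types must be >= 1")
    q = (np.arange(m) + 0.5) / m
    phi_c = np.minimum(thr.ppf(q), 1.0)
    # enforce strict monotonicity in pathological near-degenerate cases
    phi_c = np.maximum.accumulate(phi_c)
    if np.any(np.diff(phi_c) <= 0):
        keep = np.concatenate([[True], np.diff(phi_c) > 0])
        phi_c = phi_c[keep]
        p_c = np.full(len(phi_c), 1.0 / len(phi_c))
    else:
        p_c = np.full(m, 1.0 / m)
    return TypeScheme(phi_c=phi_c, p_c=p_c)


@dataclass
class Population:
    """Configuration-model substrate with per-node marks.

    Attributes
    ----------
    n
        Number of nodes (ids ``0..n-1``).
    indptr, indices
        CSR adjacency of the simple undirected graph.
    edges
        Unique undirected edges as an ``(E, 2)`` array with ``u < v``.
    degree
        Realised degrees (after erasure of self-loops/multi-edges).
    immune
        Boolean mask; immune nodes never adopt and carry no threshold.
    threshold
        Fractional threshold in ``(0, 1]``; NaN for immune nodes.
    ctype
        Node type: 0 for immune, ``1..M`` when a :class:`TypeScheme` was
        attached, -1 for non-immune nodes without a type assignment.
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    edges: np.ndarray
    degree: np.ndarray
    immune: np.ndarray
    threshold: np.ndarray
    ctype: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ctype is None:
            ct = np.full(self.n, -1, dtype=np.int64)
            ct[self.immune] = 0
            self.ctype = ct

    # -- helpers -----------------------------------------------------------

    @property
    def r(self) -> float:
        """Realised immune fraction."""
        return float(self.immune.sum()) / self.n

    @property
    def mean_degree(self) -> float:
        return float(self.degree.mean())

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: np.ndarray,
        immune: np.ndarray | None = None,
        threshold: np.ndarray | None = None,
    ) -> "Population":
        """Build a population from an explicit edge array (test/empirical path)."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("edge endpoints must lie in [0, n)")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        edges = np.sort(edges, axis=1)
        if edges.size:
            edges = np.unique(edges, axis=0)
        indptr, indices, degree = _csr_from_edges(n, edges)
        if immune is None:
            immune = np.zeros(n, dtype=bool)
        if threshold is None:
            threshold = np.where(immune, np.nan, 1.0)
        return cls(
            n=n,
            indptr=indptr,
            indices=indices,
            edges=edges,
            degree=degree,
            immune=np.asarray(immune, dtype=bool),
            threshold=np.asarray(threshold, dtype=float),
        )


def _csr_from_edges(n: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if edges.size == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64), np.zeros(n, dtype=np.int64)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    degree = np.bincount(src, minlength=n).astype(np.int64)
    indptr = np.concatenate([[0], np.cumsum(degree)]).astype(np.int64)
    return indptr, dst.astype(np.int64), degree


def build_population(
    deg: DegreeModel,
    thr: ThresholdModel,
    n: int,
    r: float,
    rng: np.random.Generator,
    types: TypeScheme | None = None,
    convention: str = "density",
) -> Population:
    """Draw a configuration-model substrate with immune flags and thresholds.

    Exactly ``round(r * n)`` nodes are immune, placed uniformly at random
    (hypergeometric placement), independent of degree. Thresholds are i.i.d.
    draws from ``thr`` for non-immune nodes, independent of degree. If the
    drawn degree sequence has an odd stub sum, one node's degree is redrawn
    (logged) until the sum is even.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError("immune fraction r must lie in [0, 1]")

    degrees = deg.sample(n, rng, convention)
    redraws = 0
    while degrees.sum() % 2 == 1:
        i = int(rng.integers(n))
        degrees[i] = deg.sample(1, rng, convention)[0]
        redraws += 1
    if redraws:
        logger.info("odd stub sum: redrew %d node degree(s) to restore parity", redraws)

    # stub matching
    stubs = np.repeat(np.arange(n, dtype=np.int64), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]  # erase self-loops
    pairs = np.sort(pairs, axis=1)
    edges = np.unique(pairs, axis=0) if pairs.size else pairs  # erase multi-edges
    indptr, indices, realised = _csr_from_edges(n, edges)

    n_imm = int(round(r * n))
    immune = np.zeros(n, dtype=bool)
    immune[rng.permutation(n)[:n_imm]] = True

    threshold = np.full(n, np.nan)
    sus = ~immune
    if sus.any():
        threshold[sus] = thr.sample(int(sus.sum()), rng)

    ctype = np.full(n, -1, dtype=np.int64)
    ctype[immune] = 0
    if types is not None:
        # assign each non-immune node the type whose quantile bin holds its
        # threshold; bin edges are the cumulative type masses
        edges_q = np.concatenate([[0.0], np.cumsum(types.p_c)])
        edges_phi = thr.ppf(np.clip(edges_q, 0.0, 1.0))
        c = np.searchsorted(edges_phi[1:-1], threshold[sus], side="right") + 1
        ctype[sus] = c

    return Population(
        n=n,
        indptr=indptr,
        indices=indices,
        edges=edges,
        degree=realised,
        immune=immune,
        threshold=threshold,
        ctype=ctype,
    )


def degree_classes(
    deg: DegreeModel,
    k_lo: int = 3,
    k_hi: int = 150,
    n_classes: int = 25,
    convention: str = "density",
) -> tuple[np.ndarray, np.ndarray]:
    """Geometrically spaced degree classes for the AME, with folded tails.

    Returns representative integer degrees ``k_0 < ... < k_{M-1}`` spanning
    ``[k_lo, k_hi]`` and their probability masses under the degree law;
    mass below ``k_lo`` (above ``k_hi``) is folded into the first (last)
    class so the masses sum to one.
    """
    if not (1 <= k_lo <= k_hi):
        raise ValueError("need 1 <= k_lo <= k_hi")
    reps = np.unique(
        np.round(np.geomspace(k_lo, k_hi, n_classes)).astype(np.int64)
    )
    k, p = deg.pmf(convention)
    # boundaries halfway (geometrically) between consecutive representatives
    bounds = np.sqrt(reps[:-1].astype(float) * reps[1:].astype(float))
    cls_idx = np.searchsorted(bounds, k.astype(float), side="right")
    masses = np.zeros(len(reps))
    np.add.at(masses, cls_idx, p)
    return reps, masses
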