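"""Weighted digraphs, base topologies, ground sets and communicability.

Orientation conventions (used consistently across the package):

- Edges are ordered pairs ``(u, v)`` meaning ``u → v``, 1-based labels.
- The state matrix stores edge ``u → v`` at ``A[v-1, u-1]`` (``Aᵀ`` is the
  adjacency matrix).
- Communicability uses the binary structural matrix ``A01`` with
  ``A01[u-1, v-1] = 1`` iff ``u → v`` is an edge, i.e. the zero pattern of
  ``Aᵀ``; ``c_uv`` counts walks *from* u *to* v, length-k walks discounted
  by 1/k!.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm
from scipy.stats import spearmanr

from itnet.model import NetworkModel, sigma_at

__all__ = [
    "WeightedDigraph",
    "GroundSet",
    "build_base_topology",
    "build_ground_set",
    "verify_ground_membership",
    "communicability",
    "covariance_communicability_check",
    "random_connected_digraph",
]

Edge = tuple[int, int]


@dataclass
class WeightedDigraph:
    """Directed graph on vertices {1..n} with positive edge weights, no self-loops."""

    n: int
    weights: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one vertex")
        clean: dict[Edge, float] = {}
        for (u, v), w in self.weights.items():
            self._check_edge(u, v)
            if w <= 0:
                raise ValueError(f"edge ({u},{v}) has non-positive weight {w}")
            clean[(int(u), int(v))] = float(w)
        self.weights = clean

    def _check_edge(self, u: int, v: int):
        if not (1 <= u <= self.n and 1 <= v <= self.n):
            raise ValueError(f"edge ({u},{v}) out of vertex range 1..{self.n}")
        if u == v:
            raise ValueError(f"self-loop ({u},{v}) not allowed")

    @property
    def edges(self) -> set[Edge]:
        return set(self.weights)

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.weights

    def add_edge(self, u: int, v: int, w: float = 1.0) -> None:
        self._check_edge(u, v)
        if w <= 0:
            raise ValueError("weight must be positive")
        self.weights[(u, v)] = float(w)

    def remove_edge(self, u: int, v: int) -> None:
        del self.weights[(u, v)]

    def copy(self) -> "WeightedDigraph":
        return WeightedDigraph(self.n, dict(self.weights))

    def state_matrix(self) -> np.ndarray:
        """A with A[v-1, u-1] = w(u → v); Aᵀ is the weighted adjacency."""
        A = np.zeros((self.n, self.n))
        for (u, v), w in self.weights.items():
            A[v - 1, u - 1] = w
        return A

    def structural_matrix(self) -> np.ndarray:
        """Binary A01 with A01[u-1, v-1] = 1 iff u → v is an edge (pattern of Aᵀ)."""
        M = np.zeros((self.n, self.n))
        for u, v in self.weights:
            M[u - 1, v - 1] = 1.0
        return M

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(1, self.n + 1))
        for (u, v), w in self.weights.items():
            g.add_edge(u, v, weight=w)
        return g

    def is_weakly_connected(self) -> bool:
        return nx.is_weakly_connected(self.to_networkx())

    def to_model(
        self,
        Sigma0: np.ndarray | float = 1.0,
        B1: np.ndarray | float = 0.1,
        mu0: np.ndarray | None = None,
        cooperative: bool = True,
    ) -> NetworkModel:
        """Linear stochastic model on this graph; scalar Σ0/B1 mean scalar·I."""
        n = self.n
        if np.isscalar(Sigma0):
            Sigma0 = float(Sigma0) * np.eye(n)
        if np.isscalar(B1):
            B1 = float(B1) * np.eye(n)
        if mu0 is None:
            mu0 = np.zeros(n)
        return NetworkModel(
            A=self.state_matrix(), B1=B1, mu0=mu0, Sigma0=Sigma0,
            cooperative=cooperative,
        )


@dataclass(frozen=True)
class GroundSet:
    """Candidate edges for maximizing T_{j→i}, in deterministic lexicographic order."""

    edges: tuple[Edge, ...]
    source: int  # j
    sink: int  # i

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


def build_base_topology(n: int, j: int, i: int, weight: float = 1.0) -> WeightedDigraph:
    """Minimal weakly connected seed for the design problem.

    A tree with n−2 edges into the source j from every node other than i
    and j, plus the single edge j → i (so the sink's in-degree is 1).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if i == j:
        raise ValueError("source and sink must differ")
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"nodes must be in 1..{n}")
    g = WeightedDigraph(n)
    for v in range(1, n + 1):
        if v not in (i, j):
            g.add_edge(v, j, weight)
    g.add_edge(j, i, weight)
    return g


def build_ground_set(graph: WeightedDigraph, j: int, i: int) -> GroundSet:
    """Candidate edges whose addition raises T_{j→i}: all ordered pairs minus
    self-loops, minus existing edges, minus inflows to the sink not from the
    source (edges (v, i), v ≠ j, inflate σ_ii quadratically via direct walks
    to i while contributing little to σ_ij)."""
    if i == j:
        raise ValueError("source and sink must differ")
    n = graph.n
    out = [
        (u, v)
        for u in range(1, n + 1)
        for v in range(1, n + 1)
        if u != v and not graph.has_edge(u, v) and not (v == i and u != j)
    ]
    return GroundSet(edges=tuple(out), source=j, sink=i)


def verify_ground_membership(
    graph: WeightedDigraph,
    edge: Edge,
    j: int,
    i: int,
    Sigma0: np.ndarray | float = 1.0,
    B1: np.ndarray | float = 0.1,
    t: float = 10.0,
    probe_weight: float = 1.0,
) -> bool:
    """Check the defining marginal-covariance inequality for ground-set membership:
    adding the candidate edge must raise σ_ij strictly more than σ_ii.

    This evaluates the covariance definition directly and exists to validate
    the structural construction in :func:`build_ground_set` against it.
    """
    if graph.has_edge(*edge):
        raise ValueError(f"edge {edge} already present")
    base = graph.to_model(Sigma0=Sigma0, B1=B1)
    g2 = graph.copy()
    g2.add_edge(*edge, probe_weight)
    aug = g2.to_model(Sigma0=Sigma0, B1=B1)
    S_base = sigma_at(base, t)
    S_aug = sigma_at(aug, t)
    ii, jj = i - 1, j - 1
    d_sij = S_aug[ii, jj] - S_base[ii, jj]
    d_sii = S_aug[ii, ii] - S_base[ii, ii]
    return bool(d_sij > d_sii)


def communicability(graph: WeightedDigraph) -> np.ndarray:
    """c_uv = [exp(A01)]_uv — walks from u to v of all lengths, length k
    discounted by 1/k!. Diagonal ≥ 1 (the empty walk), all entries ≥ 0."""
    return expm(graph.structural_matrix())


def covariance_communicability_check(
    graph: WeightedDigraph,
    Sigma0: np.ndarray | float = 1.0,
    B1: np.ndarray | float = 0.1,
    t: float = 10.0,
) -> dict:
    """Diagnostic comparing exact covariances with their communicability
    surrogates σ_ij ≈ Σ_k c_ki c_kj (and σ_ii ≈ Σ_k c²_ki) on a unit-weight
    view of the graph.

    Returns the exact Σ, the surrogate CᵀC, and the Spearman rank
    correlation between their off-diagonal entries (1.0 by convention when
    there are fewer than two distinct off-diagonal entries).
    """
    unit = WeightedDigraph(graph.n, {e: 1.0 for e in graph.edges})
    S = sigma_at(unit.to_model(Sigma0=Sigma0, B1=B1), t)
    C = communicability(unit)
    approx = C.T @ C  # (i,j) entry = Σ_k c_ki c_kj
    mask = ~np.eye(graph.n, dtype=bool)
    x, y = S[mask], approx[mask]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = 1.0
    else:
        rho = float(spearmanr(x, y).statistic)
    return {"sigma": S, "approx": approx, "spearman": rho}


def random_connected_digraph(
    n: int, m: int, seed, weight: float = 1.0
) -> WeightedDigraph:
    """Random weakly connected digraph with exactly m distinct directed edges.

    A uniformly random labelled spanning tree is drawn for the undirected
    skeleton, each tree edge is oriented by a fair coin, and the remaining
    m − (n−1) edges are sampled uniformly without replacement from the
    unused ordered pairs. Weak connectivity is guaranteed by the spanning
    tree and re-checked defensively.
    """
    if m < n - 1 or m > n * (n - 1):
        raise ValueError(f"infeasible edge count m={m} for n={n}")
    rng = np.random.default_rng(seed)
    while True:
        edges: set[Edge] = set()
        # random labelled tree via a random Prüfer sequence
        if n == 2:
            tree = [(1, 2)]
        elif n == 1:
            tree = []
        else:
            prufer = [int(x) for x in rng.integers(1, n + 1, size=n - 2)]
            tree = _tree_from_prufer(prufer, n)
        for a, b in tree:
            if rng.random() < 0.5:
                edges.add((a, b))
            else:
                edges.add((b, a))
        pool = [
            (u, v)
            for u in range(1, n + 1)
            for v in range(1, n + 1)
            if u != v and (u, v) not in edges
        ]
        extra = m - len(edges)
        idx = rng.choice(len(pool), size=extra, replace=False)
        for k in idx:
            edges.add(pool[int(k)])
        g = WeightedDigraph(n, {e: weight for e in edges})
        if g.is_weakly_connected():
            return g


def _tree_from_prufer(prufer: list[int], n: int) -> list[Edge]:
    import heapq

    degree = {v: 1 for v in range(1, n + 1)}
    for x in prufer:
        degree[x] += 1
    edges = []
    heap = [v for v in degree if degree[v] == 1]
    heapq.heapify(heap)
    for x in prufer:
        leaf = heapq.heappop(heap)
        edges.append((leaf, x))
        degree[leaf] -= 1
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(heap, x)
    a, b = sorted(heap)
    edges.append((a, b))
    return edges
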