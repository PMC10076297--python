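"""Information-transfer centralities.

Cause centrality 𝒯_j sums the transfers a node sends (node-to-network
influence), effect centrality ℛ_j sums the transfers it receives, and the
Information Transfer Edge Centrality of an edge u → v is ec = 𝒯_u · ℛ_v:
an edge matters most when it leaves a strong sender and enters a strong
receiver. All quantities are time-indexed through Σ(t) and evaluated at a
single time t (default 10, the package-wide default evaluation time; the
ranking of transfers is invariant to this choice — see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from itnet.model import (
    DegenerateVarianceError,
    NetworkModel,
    VARIANCE_TOL,
    sigma_at,
)

__all__ = [
    "CentralityScores",
    "ratio_matrix",
    "cause_centrality",
    "effect_centrality",
    "itec",
    "compute_centralities",
]


@dataclass(frozen=True)
class CentralityScores:
    cause: np.ndarray  # 𝒯, per node (index 0 = node 1)
    effect: np.ndarray  # ℛ, per node
    itec: dict[tuple[int, int], float]  # per ordered pair (1-based)
    time: float


def ratio_matrix(Sigma: np.ndarray) -> np.ndarray:
    """M(i, j) = Σ(i, j)/Σ(i, i): row-normalized covariance, unit diagonal.

    Generally asymmetric although Σ is symmetric.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    d = np.diag(Sigma)
    if np.any(d <= VARIANCE_TOL):
        bad = int(np.argmin(d)) + 1
        raise DegenerateVarianceError(f"zero variance at node {bad}")
    return Sigma / d[:, None]


def cause_centrality(model: NetworkModel, t: float = 10.0) -> np.ndarray:
    """𝒯_j = Σ_k T_{j→k} = Σ_k A[k, j] M(k, j) (column-j inner product)."""
    M = ratio_matrix(sigma_at(model, t))
    A = model.A.copy()
    np.fill_diagonal(A, 0.0)
    return np.einsum("kj,kj->j", A, M)


def effect_centrality(model: NetworkModel, t: float = 10.0) -> np.ndarray:
    """ℛ_j = Σ_k T_{k→j} = Σ_k A[j, k] M(j, k) (row-j inner product)."""
    M = ratio_matrix(sigma_at(model, t))
    A = model.A.copy()
    np.fill_diagonal(A, 0.0)
    return np.einsum("jk,jk->j", A, M)


def itec(
    model: NetworkModel,
    t: float = 10.0,
    edges: list[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], float]:
    """ITEC ec(u → v) = 𝒯_u · ℛ_v for each requested ordered pair.

    By default scores the edges present in A (off-diagonal nonzeros); pass
    ``edges`` to score arbitrary candidate pairs. Ranking ties are broken
    lexicographically by (u, v) wherever the package sorts these scores.
    """
    scores = compute_centralities(model, t, edges=edges)
    return scores.itec


def compute_centralities(
    model: NetworkModel,
    t: float = 10.0,
    edges: list[tuple[int, int]] | None = None,
) -> CentralityScores:
    """All three centralities from a single covariance evaluation."""
    M = ratio_matrix(sigma_at(model, t))
    A = model.A.copy()
    np.fill_diagonal(A, 0.0)
    cause = np.einsum("kj,kj->j", A, M)
    effect = np.einsum("jk,jk->j", A, M)
    if edges is None:
        edges = [
            (u + 1, v + 1)
            for v in range(model.n)
            for u in range(model.n)
            if u != v and A[v, u] != 0.0
        ]
    ec = {(u, v): float(cause[u - 1] * effect[v - 1]) for (u, v) in edges}
    return CentralityScores(cause=cause, effect=effect, itec=ec, time=t)
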