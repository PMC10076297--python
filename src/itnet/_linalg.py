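"""Internal linear-algebra helpers for Gaussian covariance propagation.

The state covariance of ``dx = Ax dt + B1 dw`` obeys the differential
Lyapunov equation ``dΣ/dt = AΣ + ΣAᵀ + B1B1ᵀ`` with the closed form

    Σ(t) = e^{At} Σ0 e^{Aᵀt} + ∫₀ᵗ e^{As} Q e^{Aᵀs} ds,   Q = B1B1ᵀ.

The integral term is evaluated through a single matrix exponential of the
augmented block matrix ``[[A, Q], [0, -Aᵀ]]`` (Van Loan's construction):
with ``expm(t·M) = [[F, G], [0, H]]`` one has ``∫₀ᵗ e^{As}Q e^{Aᵀs}ds = G Fᵀ``.
All routines accept stacked inputs ``(..., n, n)`` so that batches of
candidate topologies are propagated in one vectorized call.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

__all__ = ["covariance_closed_form", "symmetrize_psd"]


def covariance_closed_form(
    A: np.ndarray, Q: np.ndarray, Sigma0: np.ndarray, t: float
) -> np.ndarray:
    """Σ(t) for ``dx = Ax dt + B1 dw`` with ``Q = B1 B1ᵀ``, batched over leading axes.

    Parameters
    ----------
    A : (..., n, n) state matrices.
    Q : (n, n) or (..., n, n) noise covariance rate ``B1 B1ᵀ``.
    Sigma0 : (n, n) or (..., n, n) initial covariance.
    t : evaluation time, ``t >= 0``.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[-1]
    Q = np.broadcast_to(np.asarray(Q, dtype=float), A.shape)
    batch = A.shape[:-2]
    M = np.zeros(batch + (2 * n, 2 * n))
    M[..., :n, :n] = A
    M[..., :n, n:] = Q
    M[..., n:, n:] = -np.swapaxes(A, -1, -2)
    E = expm(t * M)
    F = E[..., :n, :n]  # e^{At}
    G = E[..., :n, n:]
    Ft = np.swapaxes(F, -1, -2)
    Sigma = F @ (Sigma0 @ Ft) + G @ Ft
    return 0.5 * (Sigma + np.swapaxes(Sigma, -1, -2))


def symmetrize_psd(S: np.ndarray, neg_tol: float = 1e-10) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues produced by roundoff.

    The tolerance is relative to the spectral scale of each matrix
    (covariances of unstable systems reach enormous magnitudes, where an
    absolute test would be meaningless): eigenvalues in
    ``[-neg_tol·scale, 0)`` are clipped to 0; anything below raises, since
    that indicates a genuinely indefinite matrix rather than roundoff.
    """
    S = 0.5 * (S + np.swapaxes(S, -1, -2))
    w, V = np.linalg.eigh(S)
    scale = np.maximum(np.abs(w).max(axis=-1, keepdims=True), 1.0)
    if np.any(w < -neg_tol * scale):
        worst = float((w / scale).min())
        raise ValueError(
            f"matrix is not positive semidefinite (min relative eigenvalue {worst:.3e})"
        )
    w = np.clip(w, 0.0, None)
    return (V * w[..., None, :]) @ np.swapaxes(V, -1, -2)
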