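"""Linear stochastic network model and Liang–Kleeman information transfer.

A directed network with linear time-invariant stochastic nodal dynamics

    dx(t) = A x(t) dt + B1 dw(t),      x(0) ~ N(mu0, Sigma0),

where ``Aᵀ`` is the weighted adjacency matrix: entry ``A[i, j] = a_ij`` is
the weight of the directed edge ``j → i``. For this Gaussian model the
information transfer from node j to node i at time t reduces to the closed
algebraic form

    T_{j→i}(t) = a_ij · σ_ij(t) / σ_ii(t),

with σ the entries of the state covariance Σ(t). Node labels are 1-based at
the public surface (matching standard graph-theory convention) and 0-based
internally; every function that takes node labels documents this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from itnet._linalg import covariance_closed_form, symmetrize_psd

__all__ = [
    "NetworkModel",
    "CovarianceTrajectory",
    "TransferValue",
    "propagate_covariance",
    "propagate_mean",
    "information_transfer",
    "transfer_matrix",
    "DegenerateVarianceError",
]

#: variance below this is treated as degenerate (division unreliable)
VARIANCE_TOL = 1e-12


class DegenerateVarianceError(ValueError):
    """Raised when a sink variance σ_ii is too small to normalize by."""


@dataclass(frozen=True)
class NetworkModel:
    """The linear stochastic system (A, B1, mu0, Sigma0).

    ``A`` may carry a nonzero diagonal (nodal self-damping, as produced by
    phase reduction of oscillator networks); self-loops in the *adjacency*
    sense are a graph-level concept and are rejected when a model is built
    from a :class:`~itnet.graphs.WeightedDigraph`. In cooperative mode the
    off-diagonal of A must be nonnegative.
    """

    A: np.ndarray
    B1: np.ndarray
    mu0: np.ndarray
    Sigma0: np.ndarray
    cooperative: bool = False

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = A.shape[0]
        if A.shape != (n, n) or n < 1:
            raise ValueError(f"A must be square, got shape {A.shape}")
        B1 = np.atleast_2d(np.asarray(self.B1, dtype=float))
        if B1.shape[0] != n:
            raise ValueError(f"B1 must have {n} rows, got {B1.shape}")
        mu0 = np.zeros(n) if self.mu0 is None else np.asarray(self.mu0, dtype=float)
        if mu0.shape != (n,):
            raise ValueError(f"mu0 must have length {n}")
        Sigma0 = np.atleast_2d(np.asarray(self.Sigma0, dtype=float))
        if Sigma0.shape != (n, n):
            raise ValueError(f"Sigma0 must be {n}x{n}")
        for name, arr in (("A", A), ("B1", B1), ("mu0", mu0), ("Sigma0", Sigma0)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        if not np.allclose(Sigma0, Sigma0.T, atol=1e-10):
            raise ValueError("Sigma0 must be symmetric")
        if np.linalg.eigvalsh(0.5 * (Sigma0 + Sigma0.T)).min() < -1e-10:
            raise ValueError("Sigma0 must be positive semidefinite")
        if self.cooperative:
            off = A - np.diag(np.diag(A))
            if np.any(off < 0):
                raise ValueError(
                    "cooperative mode requires nonnegative off-diagonal A entries"
                )
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B1", B1)
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "Sigma0", 0.5 * (Sigma0 + Sigma0.T))

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def noise_rate(self) -> np.ndarray:
        """Q = B1 B1ᵀ, the covariance production rate of the driving noise."""
        return self.B1 @ self.B1.T


@dataclass(frozen=True)
class CovarianceTrajectory:
    """Covariance matrices Σ(t) along a strictly increasing time grid."""

    times: np.ndarray
    sigmas: np.ndarray  # shape (len(times), n, n)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0) and len(t) > 1:
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sigmas", s)

    def at(self, t: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if len(idx) == 0:
            raise KeyError(f"time {t} not on the trajectory grid")
        return self.sigmas[idx[0]]


@dataclass(frozen=True)
class TransferValue:
    """Information-transfer rate T_{j→i}(t) in nats per unit time (1-based labels)."""

    source: int
    sink: int
    time: float
    value: float


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def propagate_covariance(
    model: NetworkModel, times, method: str = "expm", rtol: float = 1e-9
) -> CovarianceTrajectory:
    """Propagate the Gaussian state covariance Σ(t) along ``times``.

    Two independent routes are provided and must agree (they are
    cross-checked in the test suite):

    - ``"expm"`` — the closed form via the augmented-exponential (Van Loan)
      construction, exact up to the matrix-exponential evaluation;
    - ``"ode"`` — adaptive integration of the vectorized differential
      Lyapunov equation ``dΣ/dt = AΣ + ΣAᵀ + B1B1ᵀ``.

    Σ(0) is returned as ``Sigma0`` exactly; every Σ(t) is symmetrized and
    eigenvalue-clipped against roundoff (negative eigenvalues beyond −1e−10
    raise).
    """
    times = _check_times(times)
    A, Q, S0 = model.A, model.noise_rate, model.Sigma0
    n = model.n
    out = np.empty((len(times), n, n))
    out[0] = S0
    if method == "expm":
        for k, t in enumerate(times[1:], start=1):
            out[k] = covariance_closed_form(A, Q, S0, float(t))
    elif method == "ode":

        def rhs(_, y):
            S = y.reshape(n, n)
            dS = A @ S + S @ A.T + Q
            return dS.ravel()

        sol = solve_ivp(
            rhs,
            (0.0, float(times[-1])),
            S0.ravel(),
            t_eval=times,
            rtol=rtol,
            atol=1e-12,
            method="RK45",
        )
        if not sol.success:
            raise RuntimeError(f"Lyapunov ODE integration failed: {sol.message}")
        out = sol.y.T.reshape(len(times), n, n)
        out[0] = S0
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("covariance propagation produced non-finite entries")
    out[1:] = symmetrize_psd(out[1:])
    return CovarianceTrajectory(times=times, sigmas=out)


def propagate_mean(model: NetworkModel, times) -> np.ndarray:
    """μ(t) = e^{At} μ0 along ``times``; returns an array of shape (len(times), n)."""
    from scipy.linalg import expm

    times = _check_times(times)
    out = np.empty((len(times), model.n))
    out[0] = model.mu0
    for k, t in enumerate(times[1:], start=1):
        out[k] = expm(model.A * float(t)) @ model.mu0
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("mean propagation produced non-finite entries")
    return out


def sigma_at(model: NetworkModel, t: float) -> np.ndarray:
    """Convenience: Σ(t) at a single time (closed form)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return model.Sigma0.copy()
    return symmetrize_psd(
        covariance_closed_form(model.A, model.noise_rate, model.Sigma0, float(t))
    )


def information_transfer(
    model: NetworkModel, j: int, i: int, t: float, Sigma: np.ndarray | None = None
) -> TransferValue:
    """Information transfer T_{j→i}(t) = a_ij σ_ij(t)/σ_ii(t).

    ``j`` (source) and ``i`` (sink) are 1-based node labels. Zero whenever
    there is no edge j→i (a_ij = 0). Self-transfer (i = j) is undefined.
    ``Sigma`` may be passed to reuse a precomputed Σ(t).
    """
    n = model.n
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"node labels must be in 1..{n}")
    if i == j:
        raise ValueError("self-transfer T_{j→j} is undefined (no self-loops)")
    if t < 0:
        raise ValueError("t must be nonnegative")
    ii, jj = i - 1, j - 1
    S = sigma_at(model, t) if Sigma is None else Sigma
    sii = S[ii, ii]
    if sii <= VARIANCE_TOL:
        raise DegenerateVarianceError(
            f"sink variance σ_{i}{i}(t) = {sii:.3e} is degenerate"
        )
    value = model.A[ii, jj] * S[ii, jj] / sii
    return TransferValue(source=j, sink=i, time=t, value=float(value))


def transfer_matrix(model: NetworkModel, t: float) -> np.ndarray:
    """n×n matrix with entry (i, j) = T_{j→i}(t); diagonal 0 by convention.

    The zero pattern matches the off-diagonal zero pattern of A.
    """
    S = sigma_at(model, t)
    d = np.diag(S)
    if np.any(d <= VARIANCE_TOL):
        bad = int(np.argmin(d)) + 1
        raise DegenerateVarianceError(f"degenerate variance at node {bad}")
    T = model.A * S / d[:, None]
    np.fill_diagonal(T, 0.0)
    return T
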