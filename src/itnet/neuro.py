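"""Wilson–Cowan oscillator networks and their phase reduction.

Each unit is a two-population (excitatory v, inhibitory u) Wilson–Cowan
oscillator; units are coupled diffusively on v (gap-junction/electrical
coupling, input ``k·(v_src − v_dst)`` into the receiver's v equation) and
driven by weak white noise. Under weak coupling the network reduces to
stochastic phase dynamics

    dφ_i = (ω_i + Σ_j γ_ij(φ_i − φ_j)) dt + Σ_k ς_ik dw_k,

with cycle-averaged coupling functions γ_ij obtained from the phase
response curve (PRC) and the membrane-potential waveforms. Around a stable
phase-locked state Δφ^ref (collective frequency Ω) the fluctuations obey a
linear stochastic model dϕ = Gϕ dt + ς dw, which plugs directly into the
information-transfer machinery of :mod:`itnet.model`.

Sign convention for G: the entries reported are those of the Jacobian of
the fluctuation dynamics (off-diagonal −γ′_ij(Δφ^ref_ij), diagonal the
negative row sum), which at a stable locked state is the nonnegative
"cooperative" orientation of the linearized coupling matrix. Entries for
absent connections are exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import root

from itnet.graphs import WeightedDigraph
from itnet.model import NetworkModel

__all__ = [
    "WilsonCowanParams",
    "OscillatorNetwork",
    "LimitCycle",
    "PhaseResponse",
    "CouplingFunction",
    "PhaseModel",
    "wilson_cowan_rhs",
    "simulate_units",
    "find_limit_cycle",
    "compute_prc",
    "coupling_function",
    "phase_locked_state",
    "linearize_phase_dynamics",
    "simulate_phase_sde",
    "to_linear_model",
    "phase_reduce",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class WilsonCowanParams:
    """Two-population Wilson–Cowan unit.

        τ_e dv/dt = −v + S_e(c1·v − c2·u + P)
        τ_i du/dt = −u + S_i(c3·v − c4·u + Q)

    with the zero-anchored sigmoid S(x) = 1/(1+e^{−a(x−θ)}) − 1/(1+e^{aθ}).
    The defaults are the classical oscillatory regime (limit cycle of
    period ≈ 7.85 time units, verified by a return-map check in the tests).
    """

    c1: float = 16.0
    c2: float = 12.0
    c3: float = 15.0
    c4: float = 3.0
    a_e: float = 1.3
    theta_e: float = 4.0
    a_i: float = 2.0
    theta_i: float = 3.7
    P: float = 1.25
    Q: float = 0.0
    tau_e: float = 1.0
    tau_i: float = 1.0


def _sigmoid(x, a, theta):
    return 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))


def wilson_cowan_rhs(p: WilsonCowanParams):
    """Vector field of a single unit; accepts states of shape (..., 2)."""

    def rhs(y):
        v, u = y[..., 0], y[..., 1]
        dv = (-v + _sigmoid(p.c1 * v - p.c2 * u + p.P, p.a_e, p.theta_e)) / p.tau_e
        du = (-u + _sigmoid(p.c3 * v - p.c4 * u + p.Q, p.a_i, p.theta_i)) / p.tau_i
        return np.stack([dv, du], axis=-1)

    return rhs


def _rk4(rhs, y, dt, n_steps, record=False):
    out = [np.array(y, copy=True)] if record else None
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if record:
            out.append(np.array(y, copy=True))
    return (y, np.array(out)) if record else y


@dataclass
class OscillatorNetwork:
    """Coupled Wilson–Cowan units.

    ``coupling`` is a weighted digraph whose edge u → v with weight k feeds
    ``k·(v_u − v_v)`` into unit v's excitatory equation. ``noise`` is the
    per-node white-noise amplitude on v (scalar or length-n). The weak
    coupling ratio (max strength / unit relaxation rate) is logged at
    construction when it exceeds ~0.2.
    """

    coupling: WeightedDigraph
    params: WilsonCowanParams | list[WilsonCowanParams] = field(
        default_factory=WilsonCowanParams
    )
    noise: float | np.ndarray = 0.0

    def __post_init__(self):
        n = self.coupling.n
        if isinstance(self.params, WilsonCowanParams):
            self.params = [self.params] * n
        if len(self.params) != n:
            raise ValueError("need one parameter set per node")
        self.noise = np.broadcast_to(np.asarray(self.noise, float), (n,)).copy()
        if self.coupling.weights:
            ratio = max(self.coupling.weights.values())
            if ratio > 0.2:
                warnings.warn(
                    f"coupling strength {ratio} is not weak relative to the "
                    "unit relaxation rate; phase reduction may be inaccurate"
                )

    @property
    def n(self) -> int:
        return self.coupling.n


def _network_rhs(net: OscillatorNetwork):
    unit_rhs = [wilson_cowan_rhs(p) for p in net.params]
    same = all(p == net.params[0] for p in net.params)
    shared = unit_rhs[0] if same else None
    edges = [(u - 1, v - 1, w) for (u, v), w in net.coupling.weights.items()]

    def rhs(y):  # y shape (..., n, 2)
        if shared is not None:
            dy = shared(y)
        else:
            dy = np.stack([unit_rhs[i](y[..., i, :]) for i in range(net.n)], axis=-2)
        for u, v, w in edges:
            dy[..., v, 0] = dy[..., v, 0] + w * (y[..., u, 0] - y[..., v, 0])
        return dy

    return rhs


def simulate_units(
    net: OscillatorNetwork,
    t_span: float,
    dt: float,
    y0: np.ndarray | None = None,
    seed: int | None = None,
):
    """Integrate the full (v, u) network: RK4 when noise-free, otherwise
    Euler–Maruyama with additive noise on each v. Returns (times, states)
    with states of shape (n_steps+1, n, 2)."""
    rhs = _network_rhs(net)
    n_steps = int(round(t_span / dt))
    if y0 is None:
        y0 = np.tile([0.1, 0.1], (net.n, 1)) + 0.01 * np.arange(net.n)[:, None]
    y0 = np.asarray(y0, dtype=float)
    times = dt * np.arange(n_steps + 1)
    noisy = np.any(net.noise > 0)
    if not noisy:
        _, traj = _rk4(rhs, y0, dt, n_steps, record=True)
    else:
        rng = np.random.default_rng(seed)
        y = y0.copy()
        traj = np.empty((n_steps + 1, net.n, 2))
        traj[0] = y
        sqdt = np.sqrt(dt)
        for s in range(n_steps):
            dw = rng.standard_normal(net.n)
            y = y + dt * rhs(y)
            y[:, 0] += net.noise * sqdt * dw
            traj[s + 1] = y
    if not np.all(np.isfinite(traj)):
        raise FloatingPointError("oscillator integration blew up")
    return times, traj


@dataclass(frozen=True)
class LimitCycle:
    """Tabulated stable limit cycle: uniform-phase samples plus a dense
    table used for asymptotic-phase lookup."""

    period: float
    samples: np.ndarray  # (n_grid, d), phase l·2π/n_grid
    dense: np.ndarray  # (dense_n, d)

    @property
    def v_waveform(self) -> np.ndarray:
        return self.samples[:, 0]

    def phase_of(self, states: np.ndarray) -> np.ndarray:
        """Asymptotic phase of on-cycle states: nearest dense sample,
        refined by projecting onto the adjacent cycle segments (sub-grid
        accuracy, needed so PRC values are not quantized to the table)."""
        states = np.atleast_2d(states)
        N = len(self.dense)
        d2 = ((states[:, None, :] - self.dense[None, :, :]) ** 2).sum(-1)
        k = d2.argmin(axis=1)
        prev_p = self.dense[(k - 1) % N]
        cur = self.dense[k]
        next_p = self.dense[(k + 1) % N]

        def project(a, b):  # fraction along segment a→b and residual dist²
            seg = b - a
            L2 = np.maximum((seg**2).sum(-1), 1e-300)
            t = np.clip(((states - a) * seg).sum(-1) / L2, 0.0, 1.0)
            res = states - (a + t[:, None] * seg)
            return t, (res**2).sum(-1)

        t_f, d_f = project(cur, next_p)
        t_b, d_b = project(prev_p, cur)
        frac = np.where(d_f <= d_b, k + t_f, k - 1 + t_b)
        return (TWO_PI * frac / N) % TWO_PI


def find_limit_cycle(
    rhs,
    y_guess=(0.1, 0.1),
    t_settle: float = 300.0,
    dt: float = 0.01,
    n_grid: int = 96,
    dense_n: int = 2048,
    n_periods_avg: int = 10,
) -> LimitCycle:
    """Settle onto the attractor, measure the period from successive upward
    crossings of the first coordinate through its mid-range value, and
    tabulate the cycle. Raises if no oscillation is detected."""
    y = _rk4(rhs, np.asarray(y_guess, float), dt, int(t_settle / dt))
    # record a long stretch to find crossings
    _, tr = _rk4(rhs, y, dt, int(200.0 / dt), record=True)
    v = tr[:, 0]
    if np.ptp(v) < 1e-3:
        raise RuntimeError("no limit cycle: first coordinate is quiescent")
    vstar = 0.5 * (v.min() + v.max())
    up = np.where((v[:-1] < vstar) & (v[1:] >= vstar))[0]
    if len(up) < n_periods_avg + 1:
        raise RuntimeError("too few oscillation cycles detected")
    # sub-step crossing times by linear interpolation
    frac = (vstar - v[up]) / (v[up + 1] - v[up])
    t_cross = (up + frac) * dt
    period = float(np.diff(t_cross)[-n_periods_avg:].mean())
    # state exactly at a crossing
    k = up[-1]
    y0 = _rk4(rhs, tr[k], float(frac[-1] * dt), 1)
    samples = np.empty((n_grid, len(y0)))
    y = y0.copy()
    h = period / n_grid
    for l in range(n_grid):
        samples[l] = y
        y = _rk4(rhs, y, h, 1)
    closure = float(np.abs(y - y0).max())
    if closure > 1e-2 * np.ptp(v):
        raise RuntimeError(f"cycle failed to close (error {closure:.3e})")
    dense = np.empty((dense_n, len(y0)))
    y = y0.copy()
    h = period / dense_n
    for l in range(dense_n):
        dense[l] = y
        y = _rk4(rhs, y, h, 1)
    return LimitCycle(period=period, samples=samples, dense=dense)


@dataclass(frozen=True)
class PhaseResponse:
    """Phase response curve Z(φ): asymptotic phase shift per unit impulse,
    one column per perturbed state coordinate (column 0 = v)."""

    phases: np.ndarray  # (n_phases,)
    Z: np.ndarray  # (n_phases, d)
    impulse: float
    cycle: LimitCycle

    @property
    def Zv(self) -> np.ndarray:
        return self.Z[:, 0]


def compute_prc(
    rhs,
    cycle: LimitCycle,
    impulse: float = 1e-3,
    n_relax_periods: int = 8,
    steps_per_period: int = 400,
) -> PhaseResponse:
    """PRC by direct perturbation: kick each cycle point by ``impulse``
    along each coordinate, let the trajectory relax back to the cycle for
    ``n_relax_periods`` periods, and read the asymptotic phase shift from
    the dense cycle table. Linearity should be verified by halving the
    impulse (the shift must scale within a couple of percent)."""
    samples = cycle.samples
    n_phases, d = samples.shape
    batches = [samples]
    for c in range(d):
        pert = samples.copy()
        pert[:, c] += impulse
        batches.append(pert)
    allstates = np.concatenate(batches, axis=0)
    dt = cycle.period / steps_per_period
    end = _rk4(rhs, allstates, dt, steps_per_period * n_relax_periods)
    ph = cycle.phase_of(end)
    ref = ph[:n_phases]
    Z = np.empty((n_phases, d))
    for c in range(d):
        dphi = ph[(c + 1) * n_phases : (c + 2) * n_phases] - ref
        dphi = (dphi + np.pi) % TWO_PI - np.pi
        Z[:, c] = dphi / impulse
    phases = TWO_PI * np.arange(n_phases) / n_phases
    return PhaseResponse(phases=phases, Z=Z, impulse=impulse, cycle=cycle)


class CouplingFunction:
    """2π-periodic tabulated coupling function γ(χ) with spline evaluation
    and derivative."""

    def __init__(self, chi: np.ndarray, values: np.ndarray):
        if len(chi) != len(values):
            raise ValueError("grid mismatch between phases and values")
        self.chi = np.asarray(chi, float)
        self.values = np.asarray(values, float)
        x = np.append(self.chi, self.chi[0] + TWO_PI)
        y = np.append(self.values, self.values[0])
        self._spline = CubicSpline(x, y, bc_type="periodic")
        self._dspline = self._spline.derivative()

    def __call__(self, x):
        return self._spline(np.mod(x, TWO_PI))

    def derivative(self, x):
        return self._dspline(np.mod(x, TWO_PI))


def coupling_function(
    prc: PhaseResponse,
    v_src: np.ndarray,
    v_dst: np.ndarray | None = None,
    strength: float = 1.0,
) -> CouplingFunction:
    """Cycle-averaged phase coupling for diffusive (gap-junction) input:

        γ(χ) = (strength/T) ∫₀ᵀ Z_v(θ) · [v_src(θ − χ) − v_dst(θ)] dθ,

    tabulated on the PRC's phase grid. γ(0) = 0 whenever the waveforms are
    identical (the diffusive input vanishes pointwise), and γ scales
    linearly in the coupling strength."""
    Z = prc.Zv
    N = len(Z)
    if v_dst is None:
        v_dst = v_src
    if len(v_src) != N or len(v_dst) != N:
        raise ValueError("waveform grids must match the PRC grid")
    vals = np.array(
        [Z @ (np.roll(v_src, m) - v_dst) / N for m in range(N)]
    )
    return CouplingFunction(prc.phases, strength * vals)


@dataclass(frozen=True)
class PhaseModel:
    """Reduced phase description of an oscillator network.

    ``gamma[(i, j)]`` is the coupling function through which source j
    drives receiver i (present only for coupling edges j → i). ``dphi_ref``
    are locked phase differences relative to node 1, ``Omega`` the
    collective frequency and ``G`` the linearized (cooperative-orientation)
    coupling matrix of the phase fluctuations."""

    omega: np.ndarray
    gamma: dict[tuple[int, int], CouplingFunction]
    dphi_ref: np.ndarray
    Omega: float
    G: np.ndarray
    period: float


def _locking_residual(omega, gamma, n):
    def r(dphi):
        out = np.array(omega, dtype=float)
        for (i, j), g in gamma.items():
            out[i - 1] += g(dphi[i - 1] - dphi[j - 1])
        return out

    return r


def _phase_jacobian(gamma, dphi, n):
    J = np.zeros((n, n))
    for (i, j), g in gamma.items():
        d = float(g.derivative(dphi[i - 1] - dphi[j - 1]))
        J[i - 1, j - 1] -= d
        J[i - 1, i - 1] += d
    return J


def phase_locked_state(
    omega: np.ndarray,
    gamma: dict[tuple[int, int], CouplingFunction],
    n_starts: int = 64,
    seed: int = 0,
    tol: float = 1e-10,
):
    """Find a stable phase-locked state: Δφ (relative to node 1) such that
    ω_i + Σ_j γ_ij(Δφ_i − Δφ_j) is the same collective frequency Ω for all
    i, with all non-neutral eigenvalues of the phase Jacobian in the left
    half plane. Damped Newton (hybrid Powell) from multiple deterministic
    and seeded random starts; raises listing unstable roots if no stable
    state is found."""
    omega = np.asarray(omega, float)
    n = len(omega)
    if n == 1:
        return np.zeros(1), float(omega[0])
    r = _locking_residual(omega, gamma, n)

    def F(x):
        dphi = np.concatenate([[0.0], x])
        res = r(dphi)
        return res[1:] - res[0]

    rng = np.random.default_rng(seed)
    # structured starts: in-phase, anti-phase, parity clusters, then random
    # {0, π} cluster patterns (cluster states are the typical locks of
    # diffusively coupled relaxation oscillators) and uniform random phases
    starts = [
        np.zeros(n - 1),
        np.full(n - 1, np.pi),
        np.pi * (np.arange(1, n) % 2 == 1).astype(float),
    ]
    if n == 2:
        starts += [np.array([c]) for c in np.linspace(0, TWO_PI, 13)[1:-1]]
    starts += [np.pi * rng.integers(0, 2, n - 1).astype(float) for _ in range(n_starts)]
    starts += [rng.uniform(0, TWO_PI, n - 1) for _ in range(n_starts)]
    unstable = []
    for x0 in starts:
        sol = root(F, x0, method="hybr", tol=1e-12)
        if not sol.success or np.abs(F(sol.x)).max() > 1e-8:
            continue
        dphi = np.concatenate([[0.0], np.mod(sol.x, TWO_PI)])
        J = _phase_jacobian(gamma, dphi, n)
        ev = np.linalg.eigvals(J)
        ev = np.delete(ev, np.argmin(np.abs(ev)))  # neutral phase-shift mode
        # stability margin scaled to ‖J‖: defective near-zero eigenvalues
        # split numerically as ±√ε‖J‖ and must not count as stable
        thresh = max(tol, 1e-7 * np.linalg.norm(J, np.inf))
        if len(ev) == 0 or np.max(ev.real) < -thresh:
            res = r(dphi)
            return dphi, float(res.mean())
        unstable.append((dphi, float(np.max(ev.real))))
    raise RuntimeError(
        "no stable phase-locked state found; unstable roots (dphi, max Re λ): "
        + "; ".join(f"({np.round(d, 3)}, {m:.3g})" for d, m in unstable[:5])
    )


def linearize_phase_dynamics(
    gamma: dict[tuple[int, int], CouplingFunction],
    dphi_ref: np.ndarray,
) -> np.ndarray:
    """Linearized coupling matrix G of the phase fluctuations around the
    locked state, in the cooperative orientation: off-diagonal
    G_ij = −γ′_ij(Δφ^ref_ij) for coupling edges (exactly 0 for absent
    connections), diagonal the negative row sum, so G's rows sum to zero
    and (1, …, 1) is a neutral mode. Warns if any off-diagonal entry is
    negative (non-cooperative at this state)."""
    n = len(dphi_ref)
    G = _phase_jacobian(gamma, np.asarray(dphi_ref, float), n)
    off = G - np.diag(np.diag(G))
    if np.any(off < -1e-12):
        bad = [
            (i + 1, j + 1)
            for i in range(n)
            for j in range(n)
            if i != j and G[i, j] < -1e-12
        ]
        warnings.warn(f"non-cooperative linearized entries at {bad}")
    return G


def simulate_phase_sde(
    omega: np.ndarray,
    gamma: dict[tuple[int, int], CouplingFunction],
    varsigma: float | np.ndarray,
    t_span: float,
    dt: float,
    phi0: np.ndarray | None = None,
    seed: int | None = None,
):
    """Euler–Maruyama paths of the full nonlinear phase dynamics.

    Returns (times, phases) with phases of shape (n_steps+1, n)."""
    omega = np.asarray(omega, float)
    n = len(omega)
    varsigma = np.broadcast_to(np.asarray(varsigma, float), (n,))
    r = _locking_residual(omega, gamma, n)
    n_steps = int(round(t_span / dt))
    phi = np.zeros(n) if phi0 is None else np.array(phi0, float)
    rng = np.random.default_rng(seed)
    out = np.empty((n_steps + 1, n))
    out[0] = phi
    sqdt = np.sqrt(dt)
    for s in range(n_steps):
        phi = phi + dt * r(phi) + varsigma * sqdt * rng.standard_normal(n)
        out[s + 1] = phi
    return dt * np.arange(n_steps + 1), out


def to_linear_model(
    G: np.ndarray,
    varsigma: float | np.ndarray = 0.001,
    Sigma0: float | np.ndarray = 0.1,
    mu0: np.ndarray | None = None,
) -> NetworkModel:
    """Wrap the linearized phase dynamics dϕ = Gϕ dt + ς dw as a
    :class:`NetworkModel` (A = G, B1 = ς), ready for transfer analysis.
    Scalars mean scalar·I."""
    G = np.asarray(G, float)
    n = G.shape[0]
    B1 = float(varsigma) * np.eye(n) if np.isscalar(varsigma) else np.asarray(varsigma)
    S0 = float(Sigma0) * np.eye(n) if np.isscalar(Sigma0) else np.asarray(Sigma0)
    return NetworkModel(
        A=G, B1=B1, mu0=np.zeros(n) if mu0 is None else mu0, Sigma0=S0
    )


def phase_reduce(
    net: OscillatorNetwork,
    n_phases: int = 96,
    impulse: float = 1e-3,
    prc_relax_periods: int = 8,
    lock_seed: int = 0,
) -> PhaseModel:
    """Full reduction pipeline: limit cycle → PRC → coupling functions →
    stable locked state → linearization. Deterministic given the grid
    sizes and the locking seed.

    Units with distinct parameters get their own cycle/PRC; frequency
    detuning beyond 1% triggers a weak-coupling warning (the averaging
    step assumes near-resonant oscillators)."""
    n = net.n
    cache: dict[tuple, tuple[LimitCycle, PhaseResponse]] = {}
    cycles, prcs = [], []
    for p in net.params:
        key = tuple(vars(p).values())
        if key not in cache:
            rhs = wilson_cowan_rhs(p)
            cyc = find_limit_cycle(rhs, n_grid=n_phases)
            prc = compute_prc(
                rhs, cyc, impulse=impulse, n_relax_periods=prc_relax_periods
            )
            cache[key] = (cyc, prc)
        cyc, prc = cache[key]
        cycles.append(cyc)
        prcs.append(prc)
    periods = np.array([c.period for c in cycles])
    if np.ptp(periods) / periods.mean() > 0.01:
        warnings.warn("unit frequencies detuned by more than 1%")
    omega = TWO_PI / periods
    gamma: dict[tuple[int, int], CouplingFunction] = {}
    for (u, v), w in net.coupling.weights.items():  # edge u → v drives unit v
        gamma[(v, u)] = coupling_function(
            prcs[v - 1], cycles[u - 1].v_waveform, cycles[v - 1].v_waveform, w
        )
    dphi, Omega = phase_locked_state(omega, gamma, seed=lock_seed)
    G = linearize_phase_dynamics(gamma, dphi)
    return PhaseModel(
        omega=omega,
        gamma=gamma,
        dphi_ref=dphi,
        Omega=Omega,
        G=G,
        period=float(periods.mean()),
    )
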