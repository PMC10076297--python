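"""Approximation guarantees for greedy transfer maximization.

The transfer objective f(S) = T_{j→i}(base ∪ S) is neither submodular nor
supermodular, so the classical (1 − 1/e) greedy guarantee does not apply.
Instead the guarantee (1/α)(1 − e^{−αγ}) is used, where γ is the
submodularity ratio (how close f is to submodular from below) and α the
curvature (how close to modular from above):

    Σ_{ω∈Ω\\S} Δ_ω(S) ≥ γ Δ_Ω(S)          for all Ω, S ⊆ E_g,
    Δ_j(S\\j ∪ Ω) ≥ (1 − α) Δ_j(S\\j)      for all Ω, S ⊆ E_g, j ∈ S\\Ω,

with Δ_X(S) = f(S ∪ X) − f(S). Exact γ and α are exponential to compute;
this module estimates them by subset sampling (γ̂ is an upper bound on γ,
α̂ a lower bound on α, so the plug-in guarantee is optimistic by sampling
and is reported as such) and evaluates the analytic transfer-ratio bounds
γ ≥ T(ω)/(T(E_g) − T(ω)), α ≤ 1 − γ_lower available on the ground set of a
base topology.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from itnet.graphs import Edge
from itnet.optimize import DesignSpec, TransferObjective

__all__ = [
    "SetFunction",
    "SampledEstimate",
    "GuaranteeEstimate",
    "AnalyticBounds",
    "marginal_gain",
    "empirical_submodularity_ratio",
    "empirical_curvature",
    "greedy_guarantee",
    "estimate_guarantee",
    "analytic_bounds",
    "non_submodularity_witness",
]

_DEGENERATE_TOL = 1e-12
#: marginal gains are differences of transfer values whose own noise floor
#: scales with the magnitudes involved (covariances grow like e^{2‖A‖t});
#: gains below this relative level are indistinguishable from roundoff
_DEGENERATE_REL = 1e-9


def _gain_tol(*values: float) -> float:
    scale = max([1.0] + [abs(v) for v in values])
    return max(_DEGENERATE_TOL, _DEGENERATE_REL * scale)


class SetFunction:
    """Cached set-function view f(S) = T_{j→i}(base ∪ S at probe weight w_ub)."""

    def __init__(self, spec: DesignSpec):
        self.spec = spec
        self.ground = tuple(spec.ground_set)
        self._obj = TransferObjective(spec)
        self._cache: dict[frozenset, float] = {}

    def __call__(self, S) -> float:
        key = frozenset(S)
        if key not in self._cache:
            self._cache[key] = self._obj.value([(e, self.spec.w_ub) for e in key])
        return self._cache[key]

    def prime(self, subsets) -> None:
        """Batch-evaluate and cache many subsets at once."""
        todo = [frozenset(S) for S in subsets]
        todo = [S for S in dict.fromkeys(todo) if S not in self._cache]
        if not todo:
            return
        vals = self._obj.value_batch(
            [[(e, self.spec.w_ub) for e in S] for S in todo]
        )
        self._cache.update(zip(todo, map(float, vals)))


def marginal_gain(f, S, X) -> float:
    """Δ_X(S) = f(S ∪ X) − f(S); X may be a single edge or an edge set."""
    S = frozenset(S)
    X = frozenset([X]) if isinstance(X, tuple) and len(X) == 2 and all(
        isinstance(x, int) for x in X
    ) else frozenset(X)
    return f(S | X) - f(S)


@dataclass(frozen=True)
class SampledEstimate:
    value: float
    ratios: tuple[float, ...]
    n_samples: int
    n_skipped: int
    seed: int


@dataclass(frozen=True)
class GuaranteeEstimate:
    gamma_hat: float
    alpha_hat: float
    bound: float
    n_samples: int
    seed: int


@dataclass(frozen=True)
class AnalyticBounds:
    gamma_lower: float
    alpha_upper: float
    T_omega: float
    T_ground: float


def _sample_subset(rng, universe):
    size = int(rng.integers(1, len(universe) + 1))
    idx = rng.choice(len(universe), size=size, replace=False)
    return frozenset(universe[int(i)] for i in idx)


def empirical_submodularity_ratio(
    f, ground_set, n_samples: int = 100, seed: int = 0
) -> SampledEstimate:
    """γ̂ = min over sampled (Ω, S) of [Σ_{ω∈Ω\\S} Δ_ω(S)] / Δ_Ω(S).

    Subset sizes are uniform on {1..|E_g|}, membership uniform. Samples with
    Δ_Ω(S) below tolerance are skipped and counted; an estimation error is
    raised if every sample is degenerate. γ̂ is monotone non-increasing in
    the number of samples (a min over more draws).
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    universe = tuple(ground_set)
    rng = np.random.default_rng(seed)
    ratios = []
    skipped = 0
    for _ in range(n_samples):
        Omega = _sample_subset(rng, universe)
        S = _sample_subset(rng, universe)
        if hasattr(f, "prime"):
            f.prime([S, S | Omega] + [S | {w} for w in Omega - S])
        dOmega = marginal_gain(f, S, Omega)
        if dOmega <= _gain_tol(f(S), f(S | Omega)):
            skipped += 1
            continue
        num = sum(marginal_gain(f, S, {w}) for w in Omega - S)
        ratios.append(num / dOmega)
    if not ratios:
        raise RuntimeError("all sampled subset pairs were degenerate")
    return SampledEstimate(
        value=float(min(ratios)),
        ratios=tuple(ratios),
        n_samples=n_samples,
        n_skipped=skipped,
        seed=seed,
    )


def empirical_curvature(
    f, ground_set, n_samples: int = 100, seed: int = 0
) -> SampledEstimate:
    """α̂ = max over sampled (Ω, S) and every j ∈ S\\Ω of
    1 − Δ_j(S\\j ∪ Ω)/Δ_j(S\\j), clipped to [0, 1]."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    universe = tuple(ground_set)
    rng = np.random.default_rng(seed)
    ratios = []
    skipped = 0
    for _ in range(n_samples):
        Omega = _sample_subset(rng, universe)
        S = _sample_subset(rng, universe)
        cands = S - Omega
        if hasattr(f, "prime"):
            pre = []
            for j in cands:
                Sj = S - {j}
                pre += [Sj, Sj | {j}, Sj | Omega, Sj | Omega | {j}]
            f.prime(pre)
        got = False
        for j in cands:
            Sj = S - {j}
            denom = marginal_gain(f, Sj, {j})
            if denom <= _gain_tol(f(Sj), f(Sj | {j})):
                continue
            num = marginal_gain(f, Sj | Omega, {j})
            ratios.append(float(np.clip(1.0 - num / denom, 0.0, 1.0)))
            got = True
        if not got:
            skipped += 1
    if not ratios:
        raise RuntimeError("all sampled subset pairs were degenerate")
    return SampledEstimate(
        value=float(max(ratios)),
        ratios=tuple(ratios),
        n_samples=n_samples,
        n_skipped=skipped,
        seed=seed,
    )


def greedy_guarantee(gamma: float, alpha: float) -> float:
    """(1/α)(1 − e^{−αγ}), the greedy fraction-of-optimum guarantee;
    continuous limit 1 − e^{−γ} as α → 0. γ = α = 1 recovers 1 − 1/e."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if alpha < 1e-12:
        return float(-math.expm1(-gamma))
    return float(-math.expm1(-alpha * gamma) / alpha)


def estimate_guarantee(
    spec: DesignSpec, n_samples: int = 100, seed: int = 0
) -> GuaranteeEstimate:
    """Sample γ̂ and α̂ on the spec's ground set and plug them into the bound."""
    f = SetFunction(spec)
    g = empirical_submodularity_ratio(f, spec.ground_set, n_samples, seed)
    a = empirical_curvature(f, spec.ground_set, n_samples, seed)
    return GuaranteeEstimate(
        gamma_hat=g.value,
        alpha_hat=a.value,
        bound=greedy_guarantee(g.value, a.value),
        n_samples=n_samples,
        seed=seed,
    )


def analytic_bounds(spec: DesignSpec) -> AnalyticBounds:
    """Transfer-ratio bounds on the ground set of a seed graph:

        γ ≥ T(ω)/(T(E_g) − T(ω)),   α ≤ 1 − T(ω)/(T(E_g) − T(ω)),

    where T(ω) is the transfer through the seed graph (whose only
    transfer-carrying inflow to the sink is the direct edge j → i) and
    T(E_g) the transfer with the entire ground set added at probe weight.
    The two bounds sum to 1 identically.
    """
    f = SetFunction(spec)
    T_omega = f(frozenset())
    T_ground = f(frozenset(spec.ground_set))
    if not (T_ground > T_omega > 0):
        raise ValueError(
            f"bounds undefined: need T(E_g) > T(ω) > 0, got "
            f"T(E_g) = {T_ground:.6g}, T(ω) = {T_omega:.6g}"
        )
    gamma_lower = T_omega / (T_ground - T_omega)
    return AnalyticBounds(
        gamma_lower=float(gamma_lower),
        alpha_upper=float(1.0 - gamma_lower),
        T_omega=float(T_omega),
        T_ground=float(T_ground),
    )


@dataclass(frozen=True)
class Witness:
    P: frozenset
    Q: frozenset
    s: Edge
    delta_P: float
    delta_Q: float


@dataclass(frozen=True)
class WitnessReport:
    submodularity_violation: Witness | None  # Δ_s(P) < Δ_s(Q), P ⊆ Q
    supermodularity_violation: Witness | None  # Δ_s(P) > Δ_s(Q)


def non_submodularity_witness(
    f,
    ground_set,
    max_subset_size: int = 3,
    universe_size: int | None = None,
    tol: float = 1e-9,
) -> WitnessReport:
    """Search small nested pairs P ⊆ Q with s ∉ Q for a diminishing-returns
    violation (witness that f is not submodular) and an increasing-returns
    violation (not supermodular). Both exist for the transfer objective on
    generic instances; a modular f yields neither. Absence on the searched
    range is reported, not an error."""
    universe = tuple(ground_set)
    if universe_size is not None:
        universe = universe[:universe_size]
    subsets = []
    for r in range(0, max_subset_size + 1):
        subsets += [frozenset(c) for c in itertools.combinations(universe, r)]
    if hasattr(f, "prime"):
        extended = list(subsets)
        for S in subsets:
            extended += [S | {s} for s in universe if s not in S]
        f.prime(extended)
    sub_w = sup_w = None
    for Q in subsets:
        for P in subsets:
            if not (P < Q):
                continue
            for s in universe:
                if s in Q:
                    continue
                dP = f(P | {s}) - f(P)
                dQ = f(Q | {s}) - f(Q)
                if sub_w is None and dP < dQ - tol:
                    sub_w = Witness(P, Q, s, dP, dQ)
                if sup_w is None and dP > dQ + tol:
                    sup_w = Witness(P, Q, s, dP, dQ)
                if sub_w is not None and sup_w is not None:
                    return WitnessReport(sub_w, sup_w)
    return WitnessReport(sub_w, sup_w)
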