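# Methods

## The model and the transfer measure

`itnet` analyzes directed networks whose node states follow linear
time-invariant stochastic dynamics

    dx(t) = A x(t) dt + B₁ dw(t),        x(0) ~ N(μ₀, Σ₀),

where `w` is standard vector white noise. The transpose of the state
matrix is the weighted adjacency matrix: `A[i][j] = a_ij` is the weight of
the directed edge j → i. The state stays Gaussian, with mean
`μ(t) = e^{At} μ₀` and covariance obeying the differential Lyapunov
equation `Σ̇ = AΣ + ΣAᵀ + B₁B₁ᵀ`.

The Liang–Kleeman information transfer from node j to node i — the rate at
which j's dynamics contribute to the evolution of i's marginal entropy —
reduces in this Gaussian setting to the closed algebraic form

    T_{j→i}(t) = a_ij · σ_ij(t) / σ_ii(t)     [nats per unit time],

with σ the entries of Σ(t). It is exactly zero when there is no edge
j → i, regardless of correlations — the property that separates it from
symmetric association measures.

**Numerics.** Σ(t) is computed two independent ways: (1) the closed form
Σ(t) = e^{At} Σ₀ e^{Aᵀt} + ∫₀ᵗ e^{As} Q e^{Aᵀs} ds, with the integral read
off one matrix exponential of the augmented block matrix
`[[A, Q], [0, −Aᵀ]]` (Van Loan's construction); (2) adaptive RK45
integration of the vectorized Lyapunov equation (relative tolerance 1e−9).
Route (1) is the default — it batches over stacked matrices, which is what
makes exhaustive subset enumeration cheap — and the test suite holds the
two routes to 1e−8 relative agreement and to 3-standard-error agreement
with 10,000 Euler–Maruyama sample paths. Every Σ is symmetrized and its
eigenvalues clipped at −1e−10 *relative to the spectral scale* (covariances
of unstable systems reach ~1e30; an absolute test would be meaningless);
anything more negative raises.

Stability of A is not assumed anywhere: all horizons are finite. The
default evaluation time is t = 10, configurable; rankings of edge sets are
essentially time-invariant (below). `A` may carry a nonzero diagonal —
nodal self-damping, as produced by phase reduction — while *graphs* never
contain self-loops; cooperative mode constrains only the off-diagonal of A
to be nonnegative. Node labels are 1-based at every public surface and in
every file format, 0-based internally.

## Ground set and base topology

For a chosen source j and sink i, the candidate edges worth adding are, by
the structural rule: every ordered pair except self-loops, existing edges,
and inflows (v, i) with v ≠ j. Direct non-source inflows to the sink
inflate σ_ii quadratically (they create short walks into i) while adding
little to σ_ij, so they depress the transfer. On the 15-node worked
instance this leaves exactly 183 candidates.

The covariance-level membership rule — "the candidate must raise σ_ij by
more than σ_ii" — is implemented verbatim in `verify_ground_membership` as
a cross-check. The two views do **not** coincide exactly: on a 6-node base
topology the absolute inequality holds only for candidates incident to the
source or the sink, while leaf-to-leaf candidates raise σ_ii by more in
absolute terms yet still *strictly increase the transfer* (the relative
growth of σ_ij beats that of σ_ii). The structural rule is the one the
optimization uses, because monotone transfer growth — not the absolute
covariance comparison — is the property that matters; the tests freeze
both facts.

The design problem seeds from a *base topology*: a tree with n−2 edges
feeding the source from every other node plus the single edge j → i, which
keeps the sink's in-degree at 1 and makes the transfer monotone
non-decreasing in added ground-set edges (verified strictly at every
greedy step at full budget).

## Communicability

`c_uv = [e^{A01}]_uv` counts walks from u to v with length-k walks
discounted by 1/k!, using the binary structural matrix (pattern of Aᵀ).
The covariance surrogates σ_ij ≈ Σ_k c_ki c_kj are rank-diagnostics, not
equalities: the surrogate's kernel corresponds to unit-time propagation,
so the Spearman agreement with exact covariances is sharp at t = 1
(ρ > 0.95 on 6-node base topologies) and degrades with horizon (ρ ≈ 0.71
at t = 10). `covariance_communicability_check` reports both sides and the
correlation rather than asserting a bound.

## Topology optimization

All problems separate *which edges* from *what weights*. Edge selection
always probes candidates at the per-edge cap w_ub; final weights follow
the boundary rule: with K_ub = ⌊w_max/w_ub⌋ and remainder
K_ubl = w_max − K_ub·w_ub, the first K_ub edges (in selection/score order)
get w_ub, the next gets K_ubl, the rest get 0 and are dropped. The optimum
sits on the boundary of the weight box (grid searches over interior
vectors never beat it in the tests). Which edge receives the remainder
matters: selection order puts it on the last-selected (least valuable)
edge, and the brute-force oracle enumerates all remainder placements so
that it dominates every heuristic by construction.

Four selection heuristics:

- **Greedy** — k passes; each pass scores every remaining candidate on top
  of the current selection and keeps the argmax (lexicographic tie-break).
- **Subgraph completion (SC)** — no scoring at all: complete all 2-node
  subgraphs containing the source (excluding the sink), then 3-node, …,
  up to n−1; leftover budget goes to outgoing edges of the sink in
  ascending target order. Rationale: short walks into the source dominate
  the communicability expansion of σ_ij.
- **Modular addition (MA)** — score each candidate once on the seed graph,
  take the k best.
- **Complementary modular addition (CMA)** — score each candidate by its
  leave-one-out loss from the full ground set, take the k best.

Measured on the 6-node design fixture (Σ0 = 5I, B = 0.1I, unit probe
weights, budgets 6–12): greedy stays ≥ 93.7% of the exhaustive optimum and
SC ≥ 93.0%; MA and CMA never beat greedy; SC and greedy differ by at most
2.6% *in either direction* — SC wins at some budgets, so the package
asserts closeness, not pointwise dominance.

**Rewiring** removes k edges and adds k new ones: first the non-source
inflows to the sink, lowest ITEC first (when more of them qualify than
the budget needs, any choice is admissible; lowest-ITEC is used for
determinism and consistency with the removal philosophy), then, if the budget is not exhausted, the
lowest-ITEC edges of the remainder; the direct edge j → i is protected;
weak-connectivity violations after removal are warned about, not fatal.
Additions run the configured heuristic on the pruned graph's ground set.

## Centralities

With M(i,j) = Σ(i,j)/Σ(i,i): cause centrality 𝒯_j = Σ_k a_kj M(k,j) is the
total transfer a node sends; effect centrality ℛ_j = Σ_k a_jk M(j,k) the
total it receives; both sums over pairwise transfers, so Σ_j 𝒯_j = Σ_j ℛ_j
identically. The information-transfer edge centrality of edge u → v is
ec = 𝒯_u·ℛ_v — cause at the tail, effect at the head. All are evaluated at
the same default t = 10 and carry t in their metadata.

## Approximation guarantees

The transfer objective f(S) = T_{j→i}(base ∪ S) is neither submodular nor
supermodular (exhaustive witnesses of both violations are found on 5-node
instances), so the classical (1−1/e) bound does not apply. The guarantee
used instead is (1/α)(1−e^{−αγ}) with submodularity ratio γ and curvature
α, both estimated by subset sampling (sizes uniform on {1..|E_g|},
membership uniform, marginal gains below 1e−12 skipped and counted). γ̂ is
a minimum over samples, hence an *over*-estimate of the true γ; α̂ a
maximum, hence an *under*-estimate of the true α — the plug-in bound is
optimistic by sampling and is reported as such.

The analytic transfer-ratio bounds γ ≥ T(ω)/(T(E_g)−T(ω)) and
α ≤ 1 − T(ω)/(T(E_g)−T(ω)) (which sum to 1 identically) are evaluated with
T(ω) the transfer of the seed graph — whose only transfer-carrying inflow
to the sink is the direct edge — and T(E_g) the transfer with the entire
ground set added at probe weight. The γ half holds in every configuration
tried. The α half does **not** hold empirically on small dense instances:
the sampled curvature reaches 0.95–0.999 there, because the objective has
genuine near-flat directions (a candidate whose marginal on some context
is ~1e−6 and collapses further once more edges are present — far above
solver noise), while the analytic bound stays near 0.95. Since α̂
under-estimates the true curvature, the true α exceeds the bound on such
instances; the bound behaves as a large-sparse-regime statement — on
large sparse ground sets random subsets essentially never hit flat
directions, and sampled curvatures stay small. The corresponding acceptance check asserts the claim
as stated and is expected to fail on its α half; the guarantee reported to
users is always the sampled one.

## Wilson–Cowan phase reduction

Each unit is the two-population Wilson–Cowan oscillator

    τ_e v̇ = −v + S_e(c1·v − c2·u + P),    τ_i u̇ = −u + S_i(c3·v − c4·u + Q)

with zero-anchored sigmoids S(x) = 1/(1+e^{−a(x−θ)}) − 1/(1+e^{aθ}).
Defaults (c1..c4 = 16, 12, 15, 3; a_e = 1.3, θ_e = 4; a_i = 2, θ_i = 3.7;
P = 1.25, Q = 0; τ = 1) sit in the classical oscillatory regime: a stable
limit cycle of period ≈ 7.85, verified by a return-map test. Units couple
diffusively on v (gap junction): edge u → v with strength k feeds
k·(v_u − v_v) into v's excitatory equation; strengths ≤ 0.1 against a unit
relaxation rate keep the coupling weak (a warning fires above 0.2).

Pipeline, all deterministic given grid sizes and the locking seed:

1. **Limit cycle** — settle 300 time units, measure the period from upward
   mid-range crossings of v (sub-step interpolated, averaged over 10
   cycles; an independent autocorrelation estimator agrees to 0.1%),
   tabulate the cycle at n_phases points plus a 2048-point dense table.
2. **PRC** — direct perturbation: kick every cycle point by ε = 1e−3 in
   each coordinate, integrate 8 periods, read the asymptotic phase shift
   against the dense table *with sub-grid projection onto the local cycle
   segment* (without it, Z is quantized to 2π/2048 per ε). Halving ε moves
   Z by < 2%; the adjoint normalization Z·F = ω holds to ~2% on average
   (up to ~12% pointwise at the relaxation spikes); a radial-isochron
   clock reproduces its analytic sinusoidal PRC to 2%.
3. **Coupling functions** — averaging:
   γ(χ) = (k/T)∫₀ᵀ Z_v(θ)[v_src(θ−χ) − v_dst(θ)]dθ, tabulated
   2π-periodically and interpolated with periodic cubic splines; γ(0) = 0
   for identical waveforms, linear in k.
4. **Locking** — solve ω_i + Σ_j γ_ij(Δφ_i − Δφ_j) = Ω (differences
   relative to node 1) by hybrid-Powell Newton from structured starts
   (in-phase, anti-phase, parity clusters, random {0, π} cluster patterns,
   uniform random) and keep only roots whose phase Jacobian has all
   non-neutral eigenvalues strictly in the left half-plane, with a
   stability margin scaled to ‖J‖ (defective near-zero eigenvalues split
   numerically as ±√ε and must not count as stable). For this oscillator
   the in-phase state is *unstable* under gap-junction coupling
   (γ′(0) > 0); pairs lock near anti-phase, and multi-oscillator fixtures
   are built so a two-cluster anti-phase state exists.
5. **Linearization** — the fluctuation dynamics dϕ = Gϕ dt + ς dw with
   off-diagonal G_ij = −γ′_ij(Δφ^ref_ij) for coupling edges (exactly 0
   otherwise) and diagonal the negative row sum, so G's rows sum to zero
   and (1,…,1) is the neutral phase-shift mode. The sign is fixed by
   requiring G to be the actual Jacobian of the phase-fluctuation
   equations; at a stable locked state this makes the off-diagonal
   nonnegative (cooperative), and any negative entry triggers a warning
   listing it. G then enters the linear framework unchanged
   (A = G, B₁ = ς; the 8-node fixture defaults to Σ₀ = 0.1·I₈ and
   B₁ = 0.001·I₈).

The 8-oscillator fixture is **synthetic benchmark wiring**: a complete
bipartite digraph between clusters {1,3,5,7}
and {2,4,6,8} in which every node receives one strong (0.1) and three weak
(0.015) inputs. Equal weighted in-strength is what makes the two-cluster
anti-phase configuration an exact locked state (the locking equations
balance node-by-node); it is stable because −γ′(π) > 0 turns the Jacobian
into minus a connected directed Laplacian. Full-network simulations
confirm the reduced model: the measured locked phase difference of a
coupled pair agrees with the prediction within 5% of a cycle, and the
stationary variance of the phase difference under weak noise matches the
linearized OU prediction ς²/(G₁₂+G₂₁) within Monte-Carlo error.

What the synthetic fixtures do **not** emulate: heterogeneous unit
parameters (supported but not exercised by defaults), chemical synapses
(the coupling is purely electrical/diffusive), noise-induced switching
between locked states (noise levels are chosen so switching is
negligible), or any particular experimentally measured circuit. Passing
tests therefore validate the
pipeline's internal consistency and its agreement with full simulations of
*this* oscillator class, not any particular biological circuit.

## Known approximations, surfaced by the tests

- Time-invariance of edge-set rankings holds exactly for 59/60 random
  nested pairs at t ∈ {1, 5, 10}; the one exception is a near-crossing
  where the late-time difference is ≲1e−4 relative. Tests assert "no
  strong sign reversal" (opposite signs both above 0.1% relative) plus
  ≥95% exact agreement.
- The covariance-level ground-set inequality and the structural rule
  disagree on leaf-to-leaf candidates (above).
- The analytic curvature upper bound fails on small dense instances
  (above).
- Monotonicity of the transfer in added edges requires the sink's
  in-degree to stay 1; update instances with other sink inflows show
  genuinely negative marginals.

## Problem sizes used by the shipped checks

Exhaustive oracles run where enumeration is exact and affordable: 4–6-node
design/update instances (≤ ~3·10⁵ covariance evaluations per instance,
batched through the augmented exponential), 100-network update batches at
6 nodes, witness searches over ≤ 3-element subsets of 8-candidate
universes, and oscillator grids of 48–96 phase points. These sizes were
chosen so each check is an exact or statistically well-powered statement
at desk scale; the library itself has no such limits.
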