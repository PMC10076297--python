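"""Wilson–Cowan simulation, phase reduction, locking and linearization."""

import numpy as np
import pytest

from itnet.graphs import WeightedDigraph
from itnet.model import transfer_matrix
from itnet.neuro import (
    CouplingFunction,
    OscillatorNetwork,
    WilsonCowanParams,
    compute_prc,
    coupling_function,
    find_limit_cycle,
    linearize_phase_dynamics,
    phase_locked_state,
    phase_reduce,
    simulate_phase_sde,
    simulate_units,
    to_linear_model,
    wilson_cowan_rhs,
)

TWO_PI = 2 * np.pi


@pytest.fixture(scope="module")
def wc_rhs():
    return wilson_cowan_rhs(WilsonCowanParams())


@pytest.fixture(scope="module")
def wc_cycle(wc_rhs):
    return find_limit_cycle(wc_rhs, n_grid=64)


@pytest.fixture(scope="module")
def wc_prc(wc_rhs, wc_cycle):
    return compute_prc(wc_rhs, wc_cycle)


class TestLimitCycle:
    def test_default_unit_oscillates_with_stable_return_map(self, wc_rhs, wc_cycle):
        assert 7.0 < wc_cycle.period < 9.0
        # return-map check: a point pushed slightly off the cycle returns
        from itnet.neuro import _rk4

        y = wc_cycle.samples[0] + np.array([0.02, 0.0])
        y = _rk4(wc_rhs, y, wc_cycle.period / 400, 400 * 6)
        dist = np.min(np.linalg.norm(wc_cycle.dense - y, axis=1))
        assert dist < 1e-3

    def test_period_by_two_independent_estimators(self, wc_rhs, wc_cycle):
        """Zero-crossing period (used by the tabulator) agrees with the
        autocorrelation-peak period to 0.1%."""
        net = OscillatorNetwork(coupling=WeightedDigraph(1))
        dt = wc_cycle.period / 500
        _, traj = simulate_units(net, t_span=20 * wc_cycle.period, dt=dt,
                                 y0=wc_cycle.samples[:1])
        v = traj[:, 0, 0] - traj[:, 0, 0].mean()
        ac = np.correlate(v, v, mode="full")[len(v) - 1:]
        lo = int(0.5 * wc_cycle.period / dt)
        hi = int(1.5 * wc_cycle.period / dt)
        lag = lo + int(np.argmax(ac[lo:hi]))
        # parabolic sub-step refinement around the peak
        a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
        frac = 0.5 * (a - c) / (a - 2 * b + c)
        period_ac = (lag + frac) * dt
        assert abs(period_ac - wc_cycle.period) / wc_cycle.period < 1e-3

    def test_quiescent_system_rejected(self):
        decay = lambda y: -y
        with pytest.raises(RuntimeError, match="quiescent"):
            find_limit_cycle(decay, y_guess=(0.3, 0.1), t_settle=50.0)


class TestPRC:
    def test_impulse_linearity_under_halving(self, wc_rhs, wc_cycle):
        z1 = compute_prc(wc_rhs, wc_cycle, impulse=1e-3).Zv
        z2 = compute_prc(wc_rhs, wc_cycle, impulse=5e-4).Zv
        scale = np.abs(z1).max()
        assert np.abs(z1 - z2).max() / scale < 0.02

    def test_adjoint_normalization_identity(self, wc_rhs, wc_cycle, wc_prc):
        """Z(φ)·F(x(φ)) = ω along the cycle (the PRC is the adjoint
        eigenfunction normalized to the rotation rate). Finite-impulse
        error concentrates at the relaxation spikes, so the identity is
        tight on average and looser pointwise there."""
        omega = TWO_PI / wc_cycle.period
        F = wc_rhs(wc_cycle.samples)
        dots = np.einsum("ij,ij->i", wc_prc.Z, F)
        rel = np.abs(dots - omega) / omega
        assert rel.mean() < 0.03
        assert rel.max() < 0.15

    def test_radial_isochron_clock_analytic_prc(self):
        """For the radial-isochron clock the PRC is exactly sinusoidal:
        Z_x = −sin θ = −y, Z_y = cos θ = x on the unit cycle."""
        om = 1.3

        def clock(y):
            x, yy = y[..., 0], y[..., 1]
            r2 = x**2 + yy**2
            return np.stack(
                [x * (1 - r2) - om * yy, yy * (1 - r2) + om * x], axis=-1
            )

        cyc = find_limit_cycle(clock, y_guess=(0.7, 0.0), t_settle=60.0,
                               n_grid=48)
        assert cyc.period == pytest.approx(TWO_PI / om, rel=1e-3)
        prc = compute_prc(clock, cyc, impulse=1e-3)
        assert np.abs(prc.Z[:, 0] + cyc.samples[:, 1]).max() < 0.02
        assert np.abs(prc.Z[:, 1] - cyc.samples[:, 0]).max() < 0.02

    def test_grid_refinement_consistency(self, wc_rhs):
        c1 = find_limit_cycle(wc_rhs, n_grid=48)
        c2 = find_limit_cycle(wc_rhs, n_grid=96)
        z1 = compute_prc(wc_rhs, c1).Zv
        z2 = compute_prc(wc_rhs, c2).Zv[::2]
        assert np.abs(z1 - z2).max() / np.abs(z2).max() < 0.01


class TestCouplingFunction:
    def test_identical_waveforms_vanish_at_zero_lag(self, wc_prc, wc_cycle):
        gam = coupling_function(wc_prc, wc_cycle.v_waveform)
        assert gam(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_strength(self, wc_prc, wc_cycle):
        g1 = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        g2 = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.2)
        chi = np.linspace(0, TWO_PI, 50)
        assert np.allclose(2 * g1(chi), g2(chi), atol=1e-12)

    def test_antisymmetric_part_has_stable_zero(self, wc_prc, wc_cycle):
        """γ̄(χ) = γ(χ) − γ(−χ) crosses zero with negative slope somewhere:
        a pair of identical units admits a stable locked state."""
        gam = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        chi = np.linspace(0, TWO_PI, 720, endpoint=False)
        gbar = gam(chi) - gam(-chi)
        sign = np.sign(gbar)
        crossings = np.nonzero(np.diff(np.concatenate([sign, sign[:1]])))[0]
        slopes = [gam.derivative(chi[c]) + gam.derivative(-chi[c])
                  for c in crossings]
        assert any(s < 0 for s in slopes)

    def test_grid_mismatch_rejected(self, wc_prc):
        with pytest.raises(ValueError):
            coupling_function(wc_prc, np.zeros(17))


class TestPhaseLocking:
    def test_single_oscillator(self):
        dphi, Omega = phase_locked_state(np.array([0.8]), {})
        assert dphi.shape == (1,) and Omega == 0.8

    def test_pair_locks_at_odd_coupling_zero(self):
        """Two identical units with a purely odd coupling lock in-phase or
        anti-phase (the only zeros of γ̄ for γ(χ) = −sin χ are 0 and π)."""
        chi = np.linspace(0, TWO_PI, 64, endpoint=False)
        g = CouplingFunction(chi, -np.sin(chi))
        gamma = {(1, 2): g, (2, 1): g}
        dphi, Omega = phase_locked_state(np.array([1.0, 1.0]), gamma)
        delta = dphi[1] % TWO_PI
        assert min(abs(delta), abs(delta - np.pi), abs(delta - TWO_PI)) < 1e-8
        assert Omega == pytest.approx(1.0, abs=1e-10)

    def test_residual_identity_at_returned_state(self, wc_prc, wc_cycle):
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g, (2, 1): g}
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, Omega = phase_locked_state(om, gamma)
        r = om.copy()
        for (i, j), gf in gamma.items():
            r[i - 1] += gf(dphi[i - 1] - dphi[j - 1])
        assert np.abs(r - Omega).max() < 1e-8

    def test_error_when_no_stable_root_exists(self):
        # an even coupling makes γ̄ ≡ 0: a continuum of neutral roots, none
        # attracting, so the solver must refuse rather than return one
        chi = np.linspace(0, TWO_PI, 64, endpoint=False)
        g = CouplingFunction(chi, np.cos(chi))
        with pytest.raises(RuntimeError, match="no stable"):
            phase_locked_state(np.array([1.0, 1.0]), {(1, 2): g, (2, 1): g})


class TestLinearization:
    def test_absent_connection_is_exact_zero(self, wc_prc, wc_cycle):
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g}  # unit 2 drives unit 1 only
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, _ = phase_locked_state(om, gamma)
        G = linearize_phase_dynamics(gamma, dphi)
        assert G[1, 0] == 0.0 and G[1, 1] == 0.0
        assert G[0, 1] > 0  # cooperative at the stable state

    def test_symmetric_pair_has_equal_entries(self, wc_prc, wc_cycle):
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g, (2, 1): g}
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, _ = phase_locked_state(om, gamma)
        G = linearize_phase_dynamics(gamma, dphi)
        assert G[0, 1] == pytest.approx(G[1, 0], rel=1e-9)

    def test_rows_sum_to_zero_and_uniform_neutral_mode(self, wc_prc, wc_cycle):
        # a chain 1↔2←…→3 with equal in-strengths locks in two clusters
        g1 = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g1, (2, 1): g1, (3, 2): g1}
        om = np.full(3, TWO_PI / wc_cycle.period)
        dphi, _ = phase_locked_state(om, gamma)
        G = linearize_phase_dynamics(gamma, dphi)
        assert np.abs(G.sum(axis=1)).max() < 1e-12
        assert np.abs(G @ np.ones(3)).max() < 1e-12


class TestSimulation:
    def test_symmetric_network_stays_symmetric(self):
        g = WeightedDigraph(2, {(1, 2): 0.05, (2, 1): 0.05})
        net = OscillatorNetwork(coupling=g)
        y0 = np.tile([0.15, 0.1], (2, 1))
        _, traj = simulate_units(net, t_span=30.0, dt=0.01, y0=y0)
        assert np.abs(traj[:, 0] - traj[:, 1]).max() < 1e-12

    def test_stochastic_paths_reproducible_from_seed(self):
        g = WeightedDigraph(2, {(1, 2): 0.05})
        net = OscillatorNetwork(coupling=g, noise=0.01)
        _, a = simulate_units(net, 10.0, 0.01, seed=5)
        _, b = simulate_units(net, 10.0, 0.01, seed=5)
        _, c = simulate_units(net, 10.0, 0.01, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_phase_sde_noise_free_keeps_locked_differences(self, wc_prc, wc_cycle):
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g, (2, 1): g}
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, Omega = phase_locked_state(om, gamma)
        _, phi = simulate_phase_sde(om, gamma, 0.0, t_span=40.0, dt=0.01,
                                    phi0=dphi)
        diffs = phi[:, 0] - phi[:, 1]
        assert np.abs(diffs - diffs[0]).max() < 1e-6
        rate = (phi[-1, 0] - phi[0, 0]) / 40.0
        assert rate == pytest.approx(Omega, rel=1e-6)

    def test_phase_sde_fluctuates_around_locked_state(self, wc_prc, wc_cycle):
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g, (2, 1): g}
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, _ = phase_locked_state(om, gamma)
        devs = []
        for seed in range(20):
            _, phi = simulate_phase_sde(om, gamma, 0.005, t_span=60.0, dt=0.01,
                                        phi0=dphi, seed=seed)
            d = phi[:, 0] - phi[:, 1]
            devs.append(d[1000:].mean())
        devs = np.array(devs) - (dphi[0] - dphi[1])
        se = devs.std(ddof=1) / np.sqrt(len(devs))
        assert abs(devs.mean()) < 3 * se + 1e-3

    def test_phase_fluctuation_variance_matches_linear_model(self, wc_prc, wc_cycle):
        """Stationary variance of the locked-pair phase difference under
        weak noise agrees with the OU prediction ς²/(G12 + G21) of the
        linearized model."""
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g, (2, 1): g}
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, _ = phase_locked_state(om, gamma)
        G = linearize_phase_dynamics(gamma, dphi)
        sigma = 0.01
        predicted = sigma**2 / (G[0, 1] + G[1, 0])
        samples = []
        for seed in range(10):
            _, phi = simulate_phase_sde(om, gamma, sigma, t_span=400.0,
                                        dt=0.02, phi0=dphi, seed=seed)
            d = phi[:, 0] - phi[:, 1]
            samples.append(d[2000:].var())
        measured = np.mean(samples)
        assert measured == pytest.approx(predicted, rel=0.25)


class TestPipeline:
    def test_to_linear_model_identity(self, wc_prc, wc_cycle):
        g = coupling_function(wc_prc, wc_cycle.v_waveform, strength=0.1)
        gamma = {(1, 2): g, (2, 1): g}
        om = np.full(2, TWO_PI / wc_cycle.period)
        dphi, _ = phase_locked_state(om, gamma)
        G = linearize_phase_dynamics(gamma, dphi)
        m = to_linear_model(G, varsigma=0.001, Sigma0=0.1)
        assert np.array_equal(m.A, G)
        S = np.eye(2) * 0.1
        T = transfer_matrix(m, 10.0)
        from itnet.model import sigma_at

        Sig = sigma_at(m, 10.0)
        assert T[0, 1] == pytest.approx(G[0, 1] * Sig[0, 1] / Sig[0, 0])

    def test_unidirectional_motif_transfer_is_structurally_zero(self):
        net = OscillatorNetwork(coupling=WeightedDigraph(2, {(2, 1): 0.1}))
        pm = phase_reduce(net, n_phases=48)
        assert pm.G[1, 0] == 0.0
        m = to_linear_model(pm.G, varsigma=0.001, Sigma0=0.1)
        for t in (1.0, 5.0, 10.0, 20.0):
            assert transfer_matrix(m, t)[1, 0] == 0.0
            assert transfer_matrix(m, t)[0, 1] > 0.0

    def test_full_simulation_confirms_phase_model_lock(self, wc_cycle):
        """Weak-coupling validity: the phase difference measured from the
        full two-unit Wilson–Cowan simulation matches the reduced model's
        locked state within 5% of a cycle."""
        net = OscillatorNetwork(coupling=WeightedDigraph(2, {(2, 1): 0.1}))
        pm = phase_reduce(net, n_phases=48)
        # start units offset and let the full system settle into lock
        y0 = np.stack([wc_cycle.samples[0], wc_cycle.samples[24]])
        dt = wc_cycle.period / 500
        _, traj = simulate_units(net, t_span=80 * wc_cycle.period, dt=dt, y0=y0)
        v = traj[-int(3 * wc_cycle.period / dt):, :, 0]
        # phase difference from the final upward mean-crossings of v
        def last_crossing(x):
            m = 0.5 * (x.min() + x.max())
            idx = np.nonzero((x[:-1] < m) & (x[1:] >= m))[0]
            k = idx[-1]
            return k + (m - x[k]) / (x[k + 1] - x[k])

        # unit 1 crossing later by Δt means its phase lags by ωΔt
        dt_cross = (last_crossing(v[:, 0]) - last_crossing(v[:, 1])) * dt
        measured = (-TWO_PI * dt_cross / wc_cycle.period) % TWO_PI
        expected = pm.dphi_ref[0] - pm.dphi_ref[1]
        diff = abs((measured - expected + np.pi) % TWO_PI - np.pi)
        assert diff < 0.05 * TWO_PI

    def test_eight_node_fixture_pipeline_and_rewire(self):
        from itnet.cli import WeightedDigraphFromG
        from itnet.io import NEURO_8NODE_EDGES
        from itnet.optimize import RewireSpec, rewire

        g = WeightedDigraph(8, {(u, v): w for u, v, w in NEURO_8NODE_EDGES})
        pm = phase_reduce(OscillatorNetwork(coupling=g), n_phases=48)
        # two-cluster anti-phase lock
        expected = np.array([0, np.pi] * 4)
        assert np.abs(np.angle(np.exp(1j * (pm.dphi_ref - expected)))).max() < 1e-6
        model = to_linear_model(pm.G, varsigma=0.001, Sigma0=0.1)
        before = transfer_matrix(model, 10.0)[6, 7]
        assert before > 0
        gg = WeightedDigraphFromG(pm.G)
        spec = RewireSpec(graph=gg, j=8, i=7, k=7, w_max=0.1, w_ub=0.015,
                          Sigma0=0.1, B1=0.001, base_A=pm.G)
        sol = rewire(spec)
        # the non-source inflows to node 7 go first
        assert {(2, 7), (4, 7), (6, 7)} <= set(sol.removed_edges)
        assert len(sol.removed_edges) == 7
        assert sol.achieved_T > sol.base_T

    def test_pipeline_deterministic(self):
        net = OscillatorNetwork(coupling=WeightedDigraph(2, {(2, 1): 0.1}))
        a = phase_reduce(net, n_phases=48)
        b = phase_reduce(net, n_phases=48)
        assert np.array_equal(a.G, b.G)
        assert np.array_equal(a.dphi_ref, b.dphi_ref)
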