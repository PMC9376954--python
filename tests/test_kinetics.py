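"""Aggregation-fragmentation kinetics: ODE, SSA, master equation, fitting."""

import numpy as np
import pytest

from twobead.kinetics import (KineticParameters, detailed_balance_residuals,
                              find_stationary_state, fit_cost, fit_kinetics,
                              gillespie_ensemble, gillespie_run,
                              master_equation_solve, master_equation_stationary,
                              monomer_start, smoluchowski_rhs, solve_kinetics)

V_BOX = 35.0 ** 3
ROW1 = KineticParameters(k_plus=7.84, k_minus=10.69e-5, q=3.07, N=72, V=V_BOX)


@pytest.fixture(scope="module")
def small_params():
    """Fast-relaxing small system for exact comparisons."""
    return KineticParameters(k_plus=1.0, k_minus=0.05, q=2.0, N=8, V=50.0)


class TestRateRule:
    def test_monomer_channels_scaled_by_q(self):
        kp, km = ROW1.rate_matrices()
        assert kp[1, 5] == pytest.approx(3.07 * 7.84)
        assert kp[5, 1] == pytest.approx(3.07 * 7.84)
        assert km[1, 1] == pytest.approx(3.07 * 10.69e-5)
        assert kp[4, 5] == pytest.approx(7.84)
        assert km[3, 6] == pytest.approx(10.69e-5)

    def test_symmetry(self):
        kp, km = ROW1.rate_matrices()
        assert np.array_equal(kp, kp.T) and np.array_equal(km, km.T)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            KineticParameters(k_plus=-1.0, k_minus=0.0, q=1.0)
        with pytest.raises(ValueError):
            KineticParameters(k_plus=1.0, k_minus=0.0, q=0.0)
        with pytest.raises(ValueError):
            KineticParameters(k_plus=1.0, k_minus=0.0, q=1.0, N=1)


class TestRateEquations:
    def test_mass_conservation_random_states(self):
        sizes = np.arange(1, 73)
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = KineticParameters(k_plus=float(rng.uniform(0.5, 10)),
                                  k_minus=float(rng.uniform(1e-5, 1e-2)),
                                  q=float(rng.uniform(0.5, 5)), N=72, V=V_BOX)
            c = rng.random(72) / p.V
            assert abs(sizes @ smoluchowski_rhs(c, p)) < 1e-15

    def test_dimer_gain_from_pure_monomers(self):
        c = np.zeros(72)
        c[0] = 72 / ROW1.V
        d = smoluchowski_rhs(c, ROW1)
        assert d[1] == pytest.approx(0.5 * 3.07 * 7.84 * c[0] ** 2)
        # and the monomer loss is exactly twice the dimer gain
        assert d[0] == pytest.approx(-2.0 * d[1])

    def test_monomer_gain_from_pure_dimers(self):
        # dimer dissociation: channel (1,1) proceeds at q k-/2 per dimer and
        # releases two monomers, so dc1/dt = q k- c2
        c = np.zeros(72)
        c[1] = 36 / ROW1.V
        d = smoluchowski_rhs(c, ROW1)
        assert d[0] == pytest.approx(3.07 * 10.69e-5 * c[1])

    def test_negative_concentrations_rejected(self):
        c = np.zeros(72)
        c[0] = -1.0
        with pytest.raises(ValueError):
            smoluchowski_rhs(c, ROW1)

    def test_constant_kernel_closed_form(self):
        # irreversible, q = 1: total cluster density follows
        # c(t) = c0 / (1 + k c0 t / 2) while truncation is negligible
        p = KineticParameters(k_plus=7.84, k_minus=0.0, q=1.0, N=72, V=V_BOX)
        c0 = 72 / p.V
        t_half = 2.0 / (p.k_plus * c0)  # time for n_c to halve
        t = np.linspace(0.0, 2.0 * t_half, 9)
        curves = solve_kinetics(p, monomer_start(72), t)
        expected = 72.0 / (1.0 + p.k_plus * c0 * t / 2.0)
        assert np.allclose(curves.mean["nc"], expected, rtol=0.01)

    def test_no_aggregation_is_a_fixed_point(self):
        p = KineticParameters(k_plus=0.0, k_minus=1.0, q=2.0, N=10, V=100.0)
        t = np.linspace(0.0, 50.0, 6)
        curves = solve_kinetics(p, monomer_start(10), t)
        assert np.allclose(curves.mean["n1"], 10.0)
        assert np.allclose(curves.mean["nc"], 10.0)

    def test_mass_conserved_by_solver(self):
        t = np.linspace(0.0, 5000.0, 40)
        _, n = solve_kinetics(ROW1, monomer_start(72), t, return_full=True)
        mass = n @ np.arange(1, 73)
        assert np.abs(mass - 72.0).max() < 1e-6 * 72

    def test_long_time_state_is_stationary(self, small_params):
        c = find_stationary_state(small_params)
        r = smoluchowski_rhs(c, small_params)
        assert np.abs(r).max() < 1e-8 * np.abs(c).max() * small_params.k_plus


class TestDetailedBalance:
    def test_stationary_state_balances_every_channel(self, small_params):
        c = find_stationary_state(small_params)
        out = detailed_balance_residuals(small_params, c)
        assert out["equilibrium"]
        assert out["max_relative"] < 1e-8

    def test_irreversible_limit_reports_nonequilibrium(self):
        p = KineticParameters(k_plus=1.0, k_minus=0.0, q=2.0, N=8, V=50.0)
        out = detailed_balance_residuals(p, np.zeros(8))
        assert not out["equilibrium"]

    def test_nonstationary_input_rejected(self, small_params):
        c = monomer_start(8)[1:] / small_params.V
        with pytest.raises(ValueError, match="stationary"):
            detailed_balance_residuals(small_params, c.astype(float))

    def test_equilibrium_independent_of_q(self, small_params):
        # q scales forward and backward monomer rates together, so the
        # equilibrium state (hence all channel ratios) does not move
        c1 = find_stationary_state(small_params)
        p2 = KineticParameters(k_plus=small_params.k_plus,
                               k_minus=small_params.k_minus,
                               q=5.0 * small_params.q,
                               N=small_params.N, V=small_params.V)
        c2 = find_stationary_state(p2)
        assert np.allclose(c1, c2, rtol=1e-7, atol=1e-12)


class TestGillespie:
    def test_mass_conserved_at_every_sample(self):
        t = np.linspace(0.0, 12000.0, 100)
        counts = gillespie_run(ROW1, monomer_start(72), t, seed=5)
        mass = counts @ np.arange(73)
        assert np.all(mass == 72)

    def test_irreversible_cluster_count_non_increasing(self):
        p = KineticParameters(k_plus=7.84, k_minus=0.0, q=3.0, N=72, V=V_BOX)
        t = np.linspace(0.0, 5000.0, 200)
        counts = gillespie_run(p, monomer_start(72), t, seed=6)
        nc = counts.sum(axis=1)
        assert np.all(np.diff(nc) <= 0)

    def test_deterministic_given_seed(self):
        t = np.linspace(0.0, 1000.0, 20)
        a = gillespie_run(ROW1, monomer_start(72), t, seed=7)
        b = gillespie_run(ROW1, monomer_start(72), t, seed=7)
        assert np.array_equal(a, b)

    def test_invalid_initial_mass_rejected(self):
        bad = np.zeros(73, dtype=int)
        bad[1] = 50
        with pytest.raises(ValueError, match="mass"):
            gillespie_run(ROW1, bad, np.array([0.0, 1.0]), seed=0)

    def test_ensemble_mean_matches_master_equation(self, small_params):
        # N = 8 exact oracle: SSA ensemble means must sit within 3 MC
        # standard errors of the master-equation means at all sample times
        t = np.linspace(0.0, 40.0, 9)
        n_reps = 3000
        curves, counts = gillespie_ensemble(small_params, monomer_start(8), t,
                                            n_reps, seed=11, return_counts=True)
        exact = master_equation_solve(small_params, monomer_start(8), t)
        for i in range(1, 9):
            mean = counts[:, :, i].mean(axis=0)
            se = counts[:, :, i].std(axis=0, ddof=1) / np.sqrt(n_reps)
            # rare sizes may never appear in the sample; floor the error
            # estimate with the exact (Poisson-like) variance of the mean
            se_floor = np.sqrt(np.maximum(exact[:, i], 0.0) / n_reps)
            gap = np.abs(mean - exact[:, i])
            assert np.all(gap <= 3.0 * np.maximum(se, se_floor) + 1e-9), f"size {i}"


class TestMasterEquation:
    def test_two_state_analytic_solution(self):
        # N = 2: monomer pair <-> dimer with rates a = q k+ / V (association)
        # and b = q k- / 2 (equal-split dissociation)
        p = KineticParameters(k_plus=2.0, k_minus=0.4, q=3.0, N=2, V=20.0)
        a = p.q * p.k_plus / p.V
        b = p.q * p.k_minus / 2.0
        t = np.linspace(0.0, 20.0, 15)
        means = master_equation_solve(p, monomer_start(2), t)
        p_dimer = a / (a + b) * (1.0 - np.exp(-(a + b) * t))
        assert np.allclose(means[:, 2], p_dimer, atol=1e-8)
        assert np.allclose(means[:, 1], 2.0 * (1.0 - p_dimer), atol=1e-8)

    def test_initial_means_equal_initial_counts(self, small_params):
        m0 = np.zeros(9, dtype=int)
        m0[2] = 3
        m0[1] = 2
        means = master_equation_solve(small_params, m0, np.array([0.0, 1.0]))
        assert np.allclose(means[0], m0)

    def test_mass_conserved(self, small_params):
        t = np.linspace(0.0, 30.0, 7)
        means = master_equation_solve(small_params, monomer_start(8), t)
        assert np.allclose(means @ np.arange(9), 8.0, atol=1e-8)

    def test_stationary_distribution_detailed_balance(self, small_params):
        # Kolmogorov: pi_a Q[a,b] = pi_b Q[b,a] for every transition pair
        pi, states = master_equation_stationary(small_params)
        _, _, _, Q = master_equation_solve(small_params, monomer_start(8),
                                           np.array([0.0, 1.0]),
                                           return_distribution=True)
        ns = len(states)
        Qoff = Q - np.diag(np.diag(Q))
        flux_fwd = pi[:, None] * Qoff
        assert np.abs(flux_fwd - flux_fwd.T).max() < 1e-12 * flux_fwd.max()

    def test_size_limit_enforced(self):
        p = KineticParameters(k_plus=1.0, k_minus=0.1, q=1.0, N=30, V=100.0)
        with pytest.raises(ValueError, match="partition"):
            master_equation_solve(p, monomer_start(30), np.array([0.0, 1.0]))


@pytest.fixture(scope="module")
def t_grid():
    return np.unique(np.concatenate([np.linspace(0, 600, 31),
                                     np.linspace(600, 12000, 58)]))


class TestFitting:
    def test_noiseless_self_consistency(self, t_grid):
        observed = solve_kinetics(ROW1, monomer_start(72), t_grid)
        guess = KineticParameters(k_plus=5.0, k_minus=2e-4, q=2.0, N=72, V=V_BOX)
        fit = fit_kinetics(observed, guess, n_starts=1)
        assert abs(fit.params.k_plus / ROW1.k_plus - 1) < 1e-3
        assert abs(fit.params.k_minus / ROW1.k_minus - 1) < 1e-3
        assert abs(fit.params.q / ROW1.q - 1) < 1e-3
        assert fit.cost < 1e-6

    def test_cost_is_objective_at_fitted_parameters(self, t_grid):
        observed = solve_kinetics(ROW1, monomer_start(72), t_grid)
        guess = KineticParameters(k_plus=6.0, k_minus=1e-4, q=3.0, N=72, V=V_BOX)
        fit = fit_kinetics(observed, guess, n_starts=1)
        assert fit.cost == pytest.approx(fit_cost(fit.params, observed), rel=1e-9)

    def test_cost_is_order_independent_plain_sum(self, t_grid):
        # the cost must be an unweighted sum over (curve, time point)
        # residuals: recomputing it from the shuffled residual set agrees
        observed = solve_kinetics(ROW1, monomer_start(72), t_grid)
        shifted = KineticParameters(k_plus=9.0, k_minus=2e-4, q=2.5, N=72, V=V_BOX)
        c1 = fit_cost(shifted, observed, rtol=1e-8)
        model = solve_kinetics(shifted, monomer_start(72), t_grid, rtol=1e-8)
        residuals = np.concatenate([(model.mean[k] - observed.mean[k]) ** 2
                                    for k in ("n1", "n2", "n3", "nc")])
        rng = np.random.default_rng(0)
        rng.shuffle(residuals)
        # the two solver invocations use slightly different atol defaults
        assert float(residuals.sum()) == pytest.approx(c1, rel=1e-5)

    def test_curve_weights_respected(self, t_grid):
        observed = solve_kinetics(ROW1, monomer_start(72), t_grid)
        shifted = KineticParameters(k_plus=9.0, k_minus=1e-4, q=3.0, N=72, V=V_BOX)
        c_n1_only = fit_cost(shifted, observed,
                             weights={"n2": 0.0, "n3": 0.0, "nc": 0.0})
        c_all = fit_cost(shifted, observed)
        assert 0 < c_n1_only < c_all
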