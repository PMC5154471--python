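"""Reference solvers: closed forms, SSA exactness, FP conservation and
cross-solver identities."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hybridrd import (SparkParams, analytic_mean_spark, fp_fast_solve,
                      fp_functional_solve, gibson_bruck_simulate,
                      richardson_extrapolate, spark_well_mixed)
from hybridrd.reference import Reaction, WellMixedModel, default_rho_max


class TestAnalyticSparkMean:
    def test_initial_value(self):
        assert analytic_mean_spark(SparkParams(), 0.0) == pytest.approx(0.1)

    def test_no_flux_keeps_baseline(self):
        p = SparkParams(J=0.0)
        t = np.linspace(0, 10, 7)
        np.testing.assert_allclose(analytic_mean_spark(p, t), p.U0,
                                   rtol=1e-12)

    def test_long_time_plateau(self):
        # Ū(∞) = U0 + J·N_ch·p∞ / (V_p |Ω|) with p∞ = 1/6
        p = SparkParams(volume=10.605)
        expect = 0.1 + 10 * 24 * (1 / 6) / (1.0 * 10.605)
        assert analytic_mean_spark(p, 1e3) == pytest.approx(expect,
                                                            rel=1e-9)
        assert expect == pytest.approx(3.872, abs=5e-4)

    def test_matches_ode_integration(self):
        # brute-force oracle: integrate the mean-field ODE numerically
        p = SparkParams(volume=10.605)

        def rhs(t, y):
            lam = p.k_on + p.k_off
            pbar = p.k_on / lam * (1 - np.exp(-lam * t))
            return p.J * p.N_ch * pbar / p.volume - p.V_p * (y[0] - p.U0)

        ts = np.linspace(0, 5, 11)
        sol = solve_ivp(rhs, (0, 5), [p.U0], t_eval=ts, rtol=1e-11,
                        atol=1e-12)
        np.testing.assert_allclose(analytic_mean_spark(p, ts), sol.y[0],
                                   atol=1e-9)


class TestGibsonBruck:
    def test_single_decay_firing_time(self, rng):
        # A→B at rate k: mean firing time 1/k
        k = 2.5
        model = WellMixedModel(
            ("A", "B"), np.array([1, 0]),
            [Reaction("decay", lambda x: k * x[0], np.array([-1, 1]),
                      (0,))])
        times = []
        for _ in range(20000):
            out = gibson_bruck_simulate(model, 50.0, rng,
                                        record_times=[50.0])
            times.append(50.0 if out["events"] == 0 else None)
        # firing times via a finer record: sample first-event times directly
        rng2 = np.random.default_rng(5)
        ft = []
        for _ in range(20000):
            t_grid = np.linspace(0, 10, 201)
            out = gibson_bruck_simulate(model, 10.0, rng2,
                                        record_times=t_grid)
            fired = np.flatnonzero(out["counts"][:, 1] > 0)
            if len(fired):
                ft.append(t_grid[fired[0]])
        ft = np.asarray(ft)
        se = ft.std() / np.sqrt(len(ft))
        assert abs(ft.mean() - 1 / k) < 3 * se + 0.05  # + grid resolution

    def test_two_state_stationary_open_probability(self, rng):
        model = WellMixedModel(
            ("open", "closed"), np.array([0, 1]),
            [Reaction("open", lambda x: 1.0 * x[1], np.array([1, -1]),
                      (1,)),
             Reaction("close", lambda x: 5.0 * x[0], np.array([-1, 1]),
                      (0,))])
        t_grid = np.arange(5.0, 100.0, 0.5)
        occ = []
        for _ in range(200):
            out = gibson_bruck_simulate(model, 100.0, rng,
                                        record_times=t_grid)
            occ.append(out["counts"][:, 0].mean())
        assert np.mean(occ) == pytest.approx(1 / 6, abs=0.01)

    def test_zero_propensity_completes_early(self, rng):
        model = WellMixedModel(
            ("A",), np.array([0]),
            [Reaction("decay", lambda x: x[0], np.array([-1]), (0,))])
        out = gibson_bruck_simulate(model, 10.0, rng, record_times=[10.0])
        assert out["events"] == 0
        assert out["counts"][0, 0] == 0

    def test_spark_network_mean_matches_separable_closed_form(self, rng):
        # separable (uncoupled) well-mixed network: E[U(t)] is the same
        # closed form as the spatial average oracle (small copy numbers
        # keep the event count modest)
        p = SparkParams(N_ch=4, volume=1.0)
        model = spark_well_mixed(p, coupled=False)
        conv = 602.0 * p.volume
        t_grid = [0.5, 1.0]
        us = np.array([gibson_bruck_simulate(model, 1.0, rng,
                                             record_times=t_grid)
                       ["counts"][:, 1] / conv for _ in range(200)])
        exact = analytic_mean_spark(p, np.asarray(t_grid))
        se = us.std(axis=0) / np.sqrt(len(us))
        assert np.all(np.abs(us.mean(axis=0) - exact) < 4 * se)


class TestFPFast:
    def test_decoupled_transport_contracts_to_origin(self):
        sol = fp_fast_solve(0.0, 1.0, 5.0, rho_max=6.0, n_rho=120,
                            tau_end=5.0)
        assert sol.p1.sum() == 0.0
        # all mass back in the lowest-ρ cell
        assert sol.p0[0] * (sol.edges[0][1] - sol.edges[0][0]) == \
            pytest.approx(1.0, abs=1e-6)

    def test_probability_conserved(self):
        for tau in (1.0, 10.0, 30.0):
            sol = fp_fast_solve(1.0, 1.0, 24.0, tau_end=tau)
            assert sol.total_probability() == pytest.approx(1.0, abs=1e-6)

    def test_rho_max_must_cover_fixed_point(self):
        with pytest.raises(ValueError, match="rho_max"):
            fp_fast_solve(1.0, 1.0, 24.0, rho_max=20.0)

    def test_stationary_moment_identity_vs_monte_carlo(self):
        # E[ρ] = a·P(ξ=1) at stationarity; brute-force jump-ODE simulation
        alpha, beta, a = 1.0, 1.0, 4.0
        sol = fp_fast_solve(alpha, beta, a, rho_max=1.2 * a, n_rho=400,
                            tau_end=25.0)
        assert sol.mean_rho() == pytest.approx(a * sol.open_probability(),
                                               rel=0.02)
        rng = np.random.default_rng(8)
        n, dt, nsteps = 20000, 0.002, 7500
        rho = np.zeros(n)
        xi = np.zeros(n, dtype=bool)
        for _ in range(nsteps):
            on = alpha * beta * (rho + 1.0)
            p_open = 1 - np.exp(-on * dt)
            p_close = 1 - np.exp(-alpha * dt)
            u = rng.random(n)
            new_xi = np.where(xi, u >= p_close, u < p_open)
            rho += dt * (a * xi - rho)     # explicit Euler between jumps
            xi = new_xi
        mc_mean = rho.mean()
        mc_se = rho.std() / np.sqrt(n)
        assert abs(sol.mean_rho() - mc_mean) < 4 * mc_se + 0.03

    def test_convergence_order_in_drho(self):
        # stationary solution: at least first-order accuracy in Δρ
        ref = fp_fast_solve(1.0, 1.0, 8.0, rho_max=9.6, n_rho=1280,
                            tau_end=20.0)
        errs = []
        for n_rho in (80, 160, 320):
            sol = fp_fast_solve(1.0, 1.0, 8.0, rho_max=9.6, n_rho=n_rho,
                                tau_end=20.0)
            fine = (ref.p0 + ref.p1).reshape(n_rho, -1).mean(axis=1)
            coarse = sol.p0 + sol.p1
            errs.append(np.abs(coarse - fine).max())
        assert errs[0] > errs[1] > errs[2]
        order = np.log2(errs[1] / errs[2])
        assert order > 0.8


class TestFPFunctional:
    def test_d_zero_matches_fast_solver(self):
        # decoupling limit: ρ_0 marginal equals the 1-ρ solve with a→a/Δx
        sol = fp_functional_solve(10.0, 1.0, 20 / 3, 0.0, 2, 2.0,
                                  rho_max=[4.0, 0.5], d_rho=0.02,
                                  tau_end=1.0)
        m1 = sol.marginal(1)
        d1 = sol.edges[1][1] - sol.edges[1][0]
        assert m1[0] * d1 == pytest.approx(1.0, abs=1e-9)
        assert np.all(m1[1:] == 0)
        ref = fp_fast_solve(10.0, 1.0, (20 / 3) / 2.0, rho_max=4.0,
                            n_rho=200, tau_end=1.0)
        diff = np.abs(sol.marginal(0) - (ref.p0 + ref.p1)).max()
        assert diff < 0.05

    def test_probability_conserved_imax2(self):
        sol = fp_functional_solve(10.0, 1.0, 20 / 3, 1.0, 2, 2.0,
                                  d_rho=0.02, tau_end=1.0)
        assert sol.total_probability() == pytest.approx(1.0, abs=1e-5)

    def test_default_rho_ranges_match_steady_state(self):
        # 1.2 × all-open steady state of the binned deterministic system
        r = default_rho_max(20 / 3, 1.0, 2, 2.0)
        assert r[0] == pytest.approx(1.2 * 25 / 9, rel=1e-12)
        assert r[1] == pytest.approx(1.2 * 5 / 9, rel=1e-12)

    def test_memory_cap_refused_with_report(self):
        with pytest.raises(MemoryError, match="cells"):
            fp_functional_solve(10.0, 1.0, 20 / 3, 1.0, 2, 2.0,
                                d_rho=1e-4, tau_end=1.0, memory_cap=1e6)

    def test_imax_limited(self):
        with pytest.raises(ValueError, match="i_max"):
            fp_functional_solve(1.0, 1.0, 1.0, 1.0, 4, 2.0, d_rho=0.1)


class TestRichardson:
    def test_constant_sequence(self):
        v, resid = richardson_extrapolate([2.5, 2.5, 2.5],
                                          [0.4, 0.2, 0.1])
        assert v == pytest.approx(2.5, abs=1e-12)

    def test_exact_linear_two_points(self):
        v, _ = richardson_extrapolate([1.0 + 0.3 * 0.4, 1.0 + 0.3 * 0.2],
                                      [0.4, 0.2])
        assert v == pytest.approx(1.0, abs=1e-13)

    def test_quadratic_sequence(self):
        steps = 1.5 ** -np.arange(6)
        vals = 1.0 + steps ** 2
        v, resid = richardson_extrapolate(vals, steps)
        assert abs(v - 1.0) < 1e-10
        assert np.abs(resid).max() < 1e-10

    def test_duplicate_steps_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            richardson_extrapolate([1.0, 2.0], [0.1, 0.1])


def test_cross_oracle_gb_vs_fp_stationary(rng):
    # well-mixed coupled single-channel model: Gibson-Bruck histogram at
    # τ=30 vs the stationary FP density (shrinking L² difference is a
    # heavier check; here the means must agree within combined error)
    alpha, beta, a = 1.0, 1.0, 4.0
    # dimensional twin: V_p=1 (τ=t), k_off=alpha, k_on=beta*k_off,
    # J/(U0·V_p·|Ω|)=a with U0=0.1, |Ω|=1
    p = SparkParams(J=a * 0.1, U0=0.1, k_on=beta * alpha, k_off=alpha,
                    V_p=1.0, N_ch=1, volume=1.0)
    model = spark_well_mixed(p, coupled=True)
    conv = 602.0 * p.volume
    us = []
    for _ in range(150):
        out = gibson_bruck_simulate(model, 30.0, rng, record_times=[30.0])
        us.append(out["counts"][0, 1] / conv)
    rho = (np.asarray(us) - p.U0) / p.U0
    sol = fp_fast_solve(alpha, beta, a, n_rho=400, tau_end=30.0)
    se = rho.std() / np.sqrt(len(rho))
    assert abs(rho.mean() - sol.mean_rho()) < 4 * se + 0.05
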