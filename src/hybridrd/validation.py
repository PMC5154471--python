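"""Desk-scale validation battery.

Each function runs one benchmark of the solver end to end — hybrid
ensembles against closed forms, next-reaction references, or direct
Fokker-Planck solves — at problem sizes chosen to finish in minutes on a
single core (the methods note documents the sizes).  The acceptance tests
and the ``scripts/acceptance.py`` entry point both call these functions,
so the numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from . import models, reference, stats
from .engine import run_ensemble
from .geometry import MOLECULES_PER_UM3
from .reference import (fp_fast_solve, fp_functional_solve,
                        gibson_bruck_simulate, spark_well_mixed)


# ---------------------------------------------------------------------------
# gated-model parameter identities (instant)
# ---------------------------------------------------------------------------

def gated_parameter_identities() -> dict:
    """Contact radius, diffusion time, rate constants and the molar
    equivalent of N = 20000 macromolecules, recomputed from their
    defining formulas."""
    p = models.GatedParams()
    return {
        "r_c_um": p.r_c,
        "tau_D_s": p.tau_D,
        "kappa_f_um3_per_s": p.kappa_f,
        "kappa_r_per_s": p.kappa_r,
        "N_total_uM": p.N_uM,
    }


# ---------------------------------------------------------------------------
# separable release-site model: error scaling in n
# ---------------------------------------------------------------------------

def spark_error_scaling(seed: int, n_total: int = 10_000) -> dict:
    """ε(n) on the separable model at Δt = 2 ms, coarse 0.5 μm mesh.

    ε = max_t |Ū_exact − ensemble mean of the spatial average|; ε(n) is
    averaged over disjoint sub-ensembles of size n, and the log-log slope
    over n = 10²…10⁴ estimates the Monte-Carlo scaling exponent.
    """
    m = models.build_spark_model(
        "separable", spacing=(0.5, 0.5, 0.5),
        extents=[[0, 10], [0, 2], [0, 0.5]], dt=2e-3, duration=5.0)
    ts = np.arange(0.0, 5.0001, 0.05)
    res = run_ensemble(m, n_total, seed, [("field_mean", "U")], ts)
    exact = reference.analytic_mean_spark(m.spark_params, res.times)
    data = res.data["field_mean:U"]
    sizes = [n for n in (100, 1000, 10_000) if n <= n_total]
    eps = {}
    for n in sizes:
        groups = data[:(n_total // n) * n].reshape(-1, n, data.shape[1])
        eps[n] = float(np.mean([stats.solution_error(g.mean(axis=0), exact)
                                for g in groups]))
    slope = stats.loglog_slope(np.array(sizes, float),
                               np.array([eps[n] for n in sizes]))
    return {"epsilon": eps, "slope": slope,
            "epsilon_largest": eps[sizes[-1]], "n_total": n_total}


# ---------------------------------------------------------------------------
# fast-diffusion coupled model vs Gibson-Bruck (well-mixed limit)
# ---------------------------------------------------------------------------

def fastdiff_comparison(seed: int, n: int = 500, t_end: float = 1.0,
                        n_bootstrap: int = 200) -> dict:
    """Hybrid p(U,t) and P(n,t) histograms vs the next-reaction reference.

    The hybrid runs the fully coupled release-site model (k_on·U/U_0,
    D = 1000 μm²/s, Δt = 0.2 ms) on a coarsened mesh (the fast-diffusion
    limit is mesh-insensitive); the reference is the exact well-mixed
    next-reaction ensemble.  The comparison scale is the bootstrap RMS L²
    fluctuation of the reference histogram.
    """
    m = models.build_spark_model("coupled", spacing=(0.505, 0.525, 0.5),
                                 dt=2e-4, duration=t_end)
    res = run_ensemble(m, n, seed,
                       [("field_mean", "U"),
                        ("state_count", "channels", "open")], [t_end])
    U_h = res.data["field_mean:U"][:, 0]
    n_h = res.data["state_count:channels:open"][:, 0]
    p = m.spark_params
    wm = spark_well_mixed(p, coupled=True,
                          molecules_per_um3=MOLECULES_PER_UM3)
    rng = np.random.default_rng([seed, 104729])
    conv = MOLECULES_PER_UM3 * p.volume
    U_g = np.empty(n)
    n_g = np.empty(n)
    for r in range(n):
        out = gibson_bruck_simulate(wm, t_end, rng, record_times=[t_end])
        n_g[r] = out["counts"][0, 0]
        U_g[r] = out["counts"][0, 1] / conv

    def compare(h_samples, g_samples, rng_b, lo, hi, bins):
        w = (hi - lo) / bins
        hh, _ = stats.density_histogram(h_samples, (lo, hi), bins)
        hg, _ = stats.density_histogram(g_samples, (lo, hi), bins)
        l2, _ = stats.l2_difference(hg, hh, w)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            resamp = g_samples[rng_b.integers(0, n, n)]
            hb, _ = stats.density_histogram(resamp, (lo, hi), bins)
            boot[b] = stats.l2_difference(hg, hb, w)[0]
        return l2, float(np.sqrt(np.mean(boot ** 2)))

    rng_b = np.random.default_rng([seed, 7919])
    umax = float(max(U_h.max(), U_g.max()) * 1.05)
    l2_U, se_U = compare(U_h, U_g, rng_b, 0.0, umax, 20)
    l2_n, se_n = compare(n_h, n_g, rng_b, -0.5, p.N_ch + 0.5, p.N_ch + 1)
    return {"l2_U": l2_U, "boot_se_U": se_U,
            "l2_n": l2_n, "boot_se_n": se_n,
            "mean_U_hybrid": float(U_h.mean()),
            "mean_U_reference": float(U_g.mean()), "n": n}


# ---------------------------------------------------------------------------
# fast-diffusion limit vs direct Fokker-Planck solve
# ---------------------------------------------------------------------------

def fp_fast_cross_check(seed: int, n: int = 2000,
                        tau_end: float = 30.0) -> dict:
    """Stationary mean of ρ: single-channel hybrid at d = 10⁴ vs the
    direct hyperbolic Chapman-Kolmogorov solve."""
    m = models.build_nondim_channel_model(spacing=(0.25, 0.25, 0.25),
                                          duration=tau_end)
    res = run_ensemble(m, n, seed, [("field_mean", "rho")], [tau_end])
    rho = res.data["field_mean:rho"][:, 0]
    sol = fp_fast_solve(1.0, 1.0, 24.0, n_rho=576, tau_end=tau_end)
    mean_h = float(rho.mean())
    mean_fp = sol.mean_rho()
    return {"mean_rho_hybrid": mean_h, "mean_rho_fp": mean_fp,
            "rel_diff_pct": 100.0 * abs(mean_h - mean_fp) / mean_fp,
            "se_hybrid": float(rho.std(ddof=1) / np.sqrt(n)), "n": n}


# ---------------------------------------------------------------------------
# finite diffusion: functional Fokker-Planck vs 2-cell hybrid
# ---------------------------------------------------------------------------

def functional_fp_comparison(seed: int, n: int = 12_500,
                             d_rhos=(1.125e-2, 7.5e-3, 5e-3)) -> dict:
    """Marginal densities p(ρ_i, τ=1) of the i_max = 2 problem.

    The hybrid side (α=10, β=1, a=20/3, d=1, Δτ=1e−4, 12,500
    realizations) is compared against the direct functional FP solve at a
    sequence of Δρ; discrepancies are L² differences in percent of the
    reference maximum, per spatial node.
    """
    m = models.build_nondim_line_model()
    res = run_ensemble(m, n, seed,
                       [("field_cell", "rho", 0), ("field_cell", "rho", 1)],
                       [1.0])
    samples = {i: res.data[f"field_cell:rho:{i}"][:, 0] for i in (0, 1)}
    out = {"d_rhos": list(d_rhos), "pct": {0: [], 1: []}, "n": n}
    for dr in d_rhos:
        sol = fp_functional_solve(10.0, 1.0, 20 / 3, 1.0, 2, 2.0,
                                  d_rho=dr, tau_end=1.0)
        for i in (0, 1):
            rmax = float(sol.edges[i][-1])
            hist, edges = stats.density_histogram(samples[i], (0.0, rmax),
                                                  20)
            ref = stats.rebin_density(sol.marginal(i), sol.edges[i], edges)
            _, pct = stats.l2_difference(ref, hist, rmax / 20)
            out["pct"][i].append(pct)
    return out


# ---------------------------------------------------------------------------
# stochastically gated binding: relaxation tail
# ---------------------------------------------------------------------------

def gated_relaxation(seed: int, n: int = 200, box: float = 2.5,
                     h: float = 0.25, dt: float = 2e-5) -> dict:
    """Scaled gated-binding run: relaxation function, late-time log-log
    slope, and the ratio to the closed-form power-law asymptote.

    The slope window [10τ_D, 45τ_D] is where the asymptote dominates the
    initial exponential; the relaxation curve is smoothed over log-spaced
    time bins before the fit.
    """
    m = models.build_gated_model(box=box, h=h, dt=dt)
    p = m.gated_params
    ts = np.unique(np.concatenate([[0.0],
                                   np.geomspace(10 * dt, m.duration, 240)]))
    res = run_ensemble(m, n, seed, [("state_count", "macro", "complex")],
                       ts)
    C = res.mean("state_count:macro:complex")
    rec = stats.RelaxationRecord(res.times, C, p.kappa_f, p.kappa_r, p.a,
                                 p.b, p.L0, p.D)
    window = (10 * p.tau_D, 45 * p.tau_D)
    out = stats.relaxation_analysis(rec)
    t, relax = out["times"], out["relaxation"]
    # log-binned smoothing inside the window
    edges = np.geomspace(window[0], window[1], 9)
    tc, rc = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi)
        if sel.any():
            tc.append(float(np.exp(np.mean(np.log(t[sel])))))
            rc.append(float(np.mean(relax[sel])))
    tc = np.array(tc)
    rc = np.array(rc)
    pos = rc > 0
    slope = (stats.loglog_slope(tc[pos], rc[pos]) if pos.sum() >= 3
             else float("nan"))
    asym = stats.relaxation_asymptote(rec, tc)
    ratio = (float(np.exp(np.mean(np.log(rc[pos] / asym[pos]))))
             if pos.sum() else float("nan"))
    return {"tail_slope": slope, "asymptote_ratio": ratio,
            "C_eq": out["C_eq"], "window_s": window,
            "times": tc.tolist(), "relaxation": rc.tolist(),
            "N": m.species[0].n, "n": n}


# ---------------------------------------------------------------------------
# spontaneous polarization
# ---------------------------------------------------------------------------

def polarity_inactive_absorbing(seed: int, n: int = 3,
                                n_steps: int = 200) -> dict:
    """Without the pre-activation pulse the inactive state is absorbing:
    every realization stays exactly at γ≡0, S≡0, U≡U₀."""
    from .engine import initialize
    m = models.build_polarity_model(
        models.PolarityParams(R=2.0, N_r=200), mesh_subdivisions=2,
        duration=n_steps * 0.01, pulse=False)
    ok = True
    for rid in range(n):
        st = initialize(m, rid, seed)
        for _ in range(n_steps):
            st.step()
        ok &= not st.particles["receptors"].state.any()
        ok &= not st.fields["S"].any()
        ok &= bool(np.allclose(st.fields["U"][m.grid.mask], 1.0,
                               rtol=1e-12))
    return {"absorbing": bool(ok), "n": n}


def polarity_pulse_run(seed: int, n: int = 8, duration: float = 60.0,
                       cluster_radius: float = 0.4) -> dict:
    """Pulse-driven scaled polarization: spatial averages stabilize while
    the number of active-receptor clusters decreases on average after the
    initial transient."""
    from .engine import initialize
    m = models.build_polarity_model(
        models.PolarityParams(R=2.0, N_r=200), mesh_subdivisions=2,
        duration=duration)
    check_times = [duration * f for f in (0.1, 0.5, 0.75, 1.0)]
    n_steps = int(round(duration / m.dt))
    check_steps = [int(round(ct / m.dt)) for ct in check_times]
    active = np.zeros((n, len(check_times)))
    clusters = np.zeros((n, len(check_times)))
    s_mean = np.zeros((n, len(check_times)))
    for rid in range(n):
        st = initialize(m, rid, seed)
        ptr = 0
        for i in range(1, n_steps + 1):
            st.step()
            if ptr < len(check_steps) and i == check_steps[ptr]:
                ps = st.particles["receptors"]
                act = ps.state == 1
                active[rid, ptr] = act.sum()
                pts = ps.cartesian(m.surface)[act]
                clusters[rid, ptr] = (stats.count_clusters(
                    pts, cluster_radius) if act.sum() else 0)
                s_mean[rid, ptr] = float(np.average(
                    st.fields["S"], weights=m.surface.areas))
                ptr += 1
    mc = clusters.mean(axis=0)
    ma = active.mean(axis=0)
    ms = s_mean.mean(axis=0)
    # stabilization: late-time relative change of the spatial averages
    s_change = abs(ms[-1] - ms[-2]) / max(ms[-1], 1e-12)
    a_change = abs(ma[-1] - ma[-2]) / max(ma[-1], 1e-12)
    return {"times": check_times, "mean_active": ma.tolist(),
            "mean_clusters": mc.tolist(), "mean_S": ms.tolist(),
            "late_S_rel_change": float(s_change),
            "late_active_rel_change": float(a_change),
            "clusters_decreasing": bool(mc[-1] < mc[0]),
            "active_fraction_final": float(ma[-1] / m.species[0].n),
            "n": n}


# ---------------------------------------------------------------------------
# engine invariants bundle (cheap)
# ---------------------------------------------------------------------------

def richardson_check() -> dict:
    steps = 1.5 ** -np.arange(6)
    vals = 1.0 + steps ** 2
    v, _ = reference.richardson_extrapolate(vals, steps)
    return {"extrapolated": float(v), "error": float(abs(v - 1.0))}
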