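"""Built-in models and ensemble statistics."""

import numpy as np
import pytest

from hybridrd import (GatedParams, PolarityParams, build_gated_model,
                      build_nondim_channel_model, build_polarity_model,
                      build_spark_model, density_histogram, initialize,
                      l2_difference, solution_error)
from hybridrd.geometry import MOLECULES_PER_UM3
from hybridrd.stats import (RelaxationRecord, count_clusters, rebin_density,
                            relaxation_analysis, relaxation_asymptote)


class TestDensityHistogram:
    def test_identical_samples_single_bin(self):
        dens, edges = density_histogram(np.full(100, 0.31), (0, 1))
        width = edges[1] - edges[0]
        assert np.count_nonzero(dens) == 1
        assert dens.max() == pytest.approx(1 / width)

    def test_integrates_to_one_exactly(self, rng):
        dens, edges = density_histogram(rng.random(1234) * 3, (0, 3.5))
        assert (dens * np.diff(edges)).sum() == pytest.approx(1.0,
                                                              abs=1e-12)

    def test_uniform_samples_flat(self, rng):
        n = 20000
        dens, _ = density_histogram(rng.random(n), (0, 1))
        se = np.sqrt((1 / 20) * (1 - 1 / 20) * n) / (n / 20)
        assert np.all(np.abs(dens - 1.0) < 4 * se)

    def test_exponential_samples_match_density(self, rng):
        n = 100_000
        samples = rng.exponential(1.0, n)
        samples = samples[samples < 10]
        dens, edges = density_histogram(samples, (0, 10))
        centers = 0.5 * (edges[1:] + edges[:-1])
        w = edges[1] - edges[0]
        # conditional density on [0,10]
        expected = np.exp(-centers) / (1 - np.exp(-10))
        p = expected * w
        se = np.sqrt(p * (1 - p) / len(samples)) / w
        assert np.all(np.abs(dens - expected) < 3 * se + 1e-3)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            density_histogram([], (0, 1))


class TestL2Difference:
    def test_identical_inputs_zero(self, rng):
        a = rng.random(20)
        assert l2_difference(a, a, 0.05) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        l2, pct = l2_difference([2.0, 0.0], [0.0, 2.0], 0.5)
        assert l2 == pytest.approx(2.0)
        assert pct == pytest.approx(100.0)

    def test_symmetry(self, rng):
        a, b = rng.random(20), rng.random(20)
        assert l2_difference(a, b, 0.1)[0] == \
            pytest.approx(l2_difference(b, a, 0.1)[0])

    def test_rebin_conserves_mass(self, rng):
        dens = rng.random(50)
        edges = np.linspace(0, 2, 51)
        dens /= (dens * np.diff(edges)).sum()
        new_edges = np.linspace(0, 2, 11)
        coarse = rebin_density(dens, edges, new_edges)
        assert (coarse * np.diff(new_edges)).sum() == pytest.approx(1.0)


class TestSolutionError:
    def test_zero_when_identical(self):
        c = np.linspace(0, 1, 10)
        assert solution_error(c, c) == 0.0

    def test_constant_offset(self):
        c = np.linspace(0, 1, 10)
        assert solution_error(c + 0.3, c) == pytest.approx(0.3)


class TestGatedParameters:
    def test_printed_identities(self):
        # contact radius, diffusion time, rate constants and the molar
        # equivalent of the macromolecule count, from their definitions
        p = GatedParams()
        assert p.r_c == pytest.approx(0.0341, abs=5e-5)
        assert p.tau_D == pytest.approx(1.163e-3, rel=5e-4)
        assert p.kappa_f == pytest.approx(0.429, abs=5e-4)
        assert p.kappa_r == pytest.approx(258.0, abs=0.5)
        assert p.N_uM == pytest.approx(3.322e-2, rel=1e-3)

    def test_default_model_geometry(self):
        m = build_gated_model()
        assert m.grid.n_cells == 50 ** 3
        assert m.species[0].n == 20000
        # half inert, half reactive at t=0
        codes = np.asarray(m.species[0].initial_state)
        assert (codes == 0).sum() == 10000 and (codes == 1).sum() == 10000

    def test_fine_mesh_variant_keeps_density(self):
        m = build_gated_model(box=1.7, h=0.034)
        assert m.species[0].n == pytest.approx(20000 * 1.7 ** 3 / 1000,
                                               abs=1)

    def test_dt_guard_at_build(self):
        with pytest.raises(ValueError, match="Δt"):
            build_gated_model(box=2.5, h=0.25, dt=0.01)

    def test_kappa_f_zero_keeps_ligand_at_baseline(self):
        from hybridrd import run_ensemble
        m = build_gated_model(box=2.5, h=0.5, dt=2e-5, duration=2e-3)
        # disable binding
        m.couplings = [c for c in m.couplings if c.kind != "mass_action"]
        m.species[0].transitions = [
            t for t in m.species[0].transitions
            if t.rate.field is None and t.to_state != "active" or
            t.from_state in ("inert", "active") and t.rate.field is None]
        res = run_ensemble(m, 2, 3, [("state_count", "macro", "complex"),
                                     ("field_mean", "L")], [2e-3])
        assert not res.data["state_count:macro:complex"].any()
        np.testing.assert_allclose(res.data["field_mean:L"], 1.0,
                                   rtol=1e-9)


class TestRelaxation:
    def test_equilibrated_curve_is_zero(self):
        rec = RelaxationRecord(np.linspace(0, 1, 5), np.full(5, 7.0),
                               0.429, 258.0, 860.0, 860.0, 602.0, 1.0)
        out = relaxation_analysis(rec)
        np.testing.assert_allclose(out["relaxation"], 0.0)

    def test_asymptote_arithmetic_vs_symbolic(self):
        # closed-form tail evaluated independently with sympy
        import sympy as sp
        kf, kr, a, b, L0, D, t = sp.symbols("kf kr a b L0 D t",
                                            positive=True)
        expr = kf * (1 + a / b) * (4 * sp.pi * D * t) ** sp.Rational(-3, 2) \
            / (kr * (1 + a / b + L0 * kf / kr) ** 2)
        subs = {kf: 0.429, kr: 258.0, a: 860.0, b: 860.0, L0: 602.0,
                D: 1.0, t: 0.01}
        expected = float(expr.subs(subs))
        rec = RelaxationRecord([0.0, 1.0], [0.0, 1.0], 0.429, 258.0,
                               860.0, 860.0, 602.0, 1.0)
        got = float(relaxation_asymptote(rec, 0.01))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_tail_slope_recovers_power_law(self):
        t = np.geomspace(0.01, 1.0, 40)
        rec = RelaxationRecord(t, 100 * (1 - 0.05 * t ** -1.5 / 20),
                               0.429, 258.0, 860.0, 860.0, 602.0, 1.0,
                               C_eq=100.0)
        out = relaxation_analysis(rec, slope_window=(0.01, 1.0))
        assert out["tail_slope"] == pytest.approx(-1.5, abs=1e-6)


class TestSparkBuilders:
    def test_separable_defaults(self):
        m = build_spark_model("separable")
        assert m.species[0].n == 24
        assert m.duration == 5.0
        assert m.species[0].mobility.is_immobile
        # field-independent rates flagged by the absence of a field ref
        assert all(r.rate.field is None for r in m.species[0].transitions)

    def test_coupled_defaults(self):
        m = build_spark_model("coupled")
        p = m.spark_params
        assert p.k_on == 0.1 and p.D == 1000.0
        on = m.species[0].transitions[0].rate
        assert on.field == "U" and on.coeff == pytest.approx(1.0)

    def test_coupled_requires_positive_baseline(self):
        from hybridrd.reference import SparkParams
        with pytest.raises(ValueError, match="U_0"):
            build_spark_model("coupled", SparkParams(k_on=0.1, U0=0.0))

    def test_nondim_single_channel(self):
        m = build_nondim_channel_model()
        assert m.grid.domain_volume == pytest.approx(1.0)
        on = m.species[0].transitions[0].rate
        assert on.coeff == on.const == 1.0          # αβ(ρ+1) with α=β=1
        assert m.fields[0].D == 1e4


class TestPolarityBuilder:
    def test_inactive_steady_state_fields(self):
        m = build_polarity_model(PolarityParams(R=2.0, N_r=50),
                                 mesh_subdivisions=1, duration=0.1)
        st = initialize(m, 0, 0)
        np.testing.assert_allclose(st.fields["S"], 0.0)
        act = st.fields["U"][m.grid.mask]
        np.testing.assert_allclose(act, 1.0)
        assert not st.particles["receptors"].state.any()

    def test_pulse_with_bad_tau_rejected(self):
        with pytest.raises(ValueError, match="time constant"):
            build_polarity_model(PolarityParams(R=2.0, N_r=10, tau_p=-1.0))

    def test_total_protein_conserved(self):
        m = build_polarity_model(PolarityParams(R=2.0, N_r=100),
                                 mesh_subdivisions=2, duration=1.0)
        st = initialize(m, 0, 2)

        def total(st):
            vol = st.fields["U"][m.grid.mask].sum() * m.grid.cell_volume \
                * MOLECULES_PER_UM3
            return vol + (st.fields["S"] * m.surface.areas).sum()

        t0 = total(st)
        for _ in range(100):
            st.step()
        assert total(st) == pytest.approx(t0, rel=1e-3)


def test_cluster_count_on_synthetic_blobs(rng):
    from hybridrd import icosphere
    mesh = icosphere(2.0, 2)
    # two antipodal caps of points
    a = rng.normal([0, 0, 2.0], 0.1, (40, 3))
    b = rng.normal([0, 0, -2.0], 0.1, (40, 3))
    pts = np.vstack([a, b])
    pts *= 2.0 / np.linalg.norm(pts, axis=1)[:, None]
    assert count_clusters(pts, radius=0.5) == 2


def test_model_config_round_trip(tmp_path):
    from hybridrd.io import load_model_yaml, save_model_yaml
    from hybridrd.io import model_to_dict
    for m in (build_spark_model("coupled"),
              build_nondim_channel_model(),
              build_gated_model(box=2.5, h=0.5, dt=2e-5),
              build_polarity_model(PolarityParams(R=2.0, N_r=20),
                                   mesh_subdivisions=1)):
        path = tmp_path / f"{m.name}.yaml"
        save_model_yaml(path, m)
        m2 = load_model_yaml(path)
        d1, d2 = model_to_dict(m), model_to_dict(m2)
        assert _deep_equal(d1, d2), m.name


def _deep_equal(a, b):
    if isinstance(a, dict):
        return set(a) == set(b) and all(_deep_equal(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)):
        return len(a) == len(b) and all(
            _deep_equal(x, y) for x, y in zip(a, b))
    if isinstance(a, float) and isinstance(b, float):
        return a == pytest.approx(b, rel=1e-12)
    return a == b
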