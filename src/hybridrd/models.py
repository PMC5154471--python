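"""Ready-to-run hybrid models: calcium-release sites, stochastically gated
reversible binding, and spontaneous cell polarization.

Each builder returns a validated :class:`~hybridrd.engine.HybridModel`
whose defaults are the reference parameter sets used throughout the
validation battery; ``preset="scaled"`` variants shrink the domain /
ensemble for desk-scale runs while keeping densities and kinetics fixed.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .engine import (FieldCoupling, FieldSpec, HybridModel, MembraneCoupling,
                     ParticleSpec)
from .geometry import (MOLECULES_PER_UM3, build_box_grid, icosphere,
                       sphere_cell_mask)
from .particles import MobilityRule, RateExpr, TransitionRule
from .reference import SparkParams


# ---------------------------------------------------------------------------
# calcium release sites (two-state channels feeding a pumped field)
# ---------------------------------------------------------------------------

def spark_channel_layout(n_ch: int, extents) -> np.ndarray:
    """Regular-grid channel positions inside a quasi-2D box.

    Synthetic fixture approximating the published regular channel
    arrangement (the original coordinates are shown graphically only);
    the separable-model statistics are position-independent.
    """
    extents = np.asarray(extents, float)
    ncol = 8
    nrow = int(math.ceil(n_ch / ncol))
    xs = extents[0, 0] + (np.arange(ncol) + 0.5) * \
        (extents[0, 1] - extents[0, 0]) / ncol
    ys = extents[1, 0] + (np.arange(nrow) + 0.5) * \
        (extents[1, 1] - extents[1, 0]) / nrow
    z = 0.5 * (extents[2, 0] + extents[2, 1])
    pts = [(x, y, z) for y in ys for x in xs]
    return np.asarray(pts[:n_ch], float)


def build_spark_model(variant: str = "separable",
                      params: Optional[SparkParams] = None,
                      spacing=(0.1, 0.1, 0.5), extents=None,
                      dt: float = 2e-3, duration: float = 5.0,
                      channel_positions: Optional[np.ndarray] = None
                      ) -> HybridModel:
    """Release-site model: immobile two-state channels in a quasi-2D box.

    variant="separable": constant opening rate k_on (closed-form ensemble
    expectation available).  variant="coupled": opening rate
    k_on·U(r,t)/U_0, the fully coupled system used with fast diffusion.
    """
    if params is None:
        params = SparkParams()
        if variant == "coupled":
            params = SparkParams(k_on=0.1, D=1000.0)
    if extents is None:
        extents = [[0.0, 10.1], [0.0, 2.1], [0.0, 0.5]]
    grid = build_box_grid(extents, spacing)
    vol = grid.domain_volume
    params = SparkParams(**{**params.__dict__, "volume": vol})
    if channel_positions is None:
        channel_positions = spark_channel_layout(params.N_ch, extents)
    if variant == "separable":
        on = RateExpr(const=params.k_on)
    elif variant == "coupled":
        if params.U0 <= 0:
            raise ValueError("coupled variant requires U_0 > 0")
        on = RateExpr(field="U", coeff=params.k_on / params.U0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    channels = ParticleSpec(
        name="channels", states=("closed", "open"), n=params.N_ch,
        initial_state="closed", positions=channel_positions,
        transitions=[TransitionRule("closed", "open", on),
                     TransitionRule.constant("open", "closed", params.k_off)])
    field = FieldSpec("U", D=params.D, initial=params.U0,
                      decay_rate=params.V_p, decay_target=params.U0)
    model = HybridModel(
        grid=grid, fields=[field], species=[channels],
        couplings=[FieldCoupling("U", "channels", "open", params.J)],
        dt=dt, duration=duration, name=f"spark-{variant}")
    model.spark_params = params
    return model


def build_nondim_channel_model(alpha: float = 1.0, beta: float = 1.0,
                               a: float = 24.0, d: float = 1e4,
                               extents=None, spacing=(0.25, 0.25, 0.25),
                               dt: float = 2e-3, duration: float = 30.0
                               ) -> HybridModel:
    """Nondimensional single-channel system for Fokker-Planck
    cross-validation: dρ/dτ = d·Δρ + a·δ(r)·ξ − ρ with channel rates
    αβ(ρ+1) (opening, evaluated in the channel's subvolume) and α."""
    if extents is None:
        extents = [[-0.5, 0.5], [-0.5, 0.5], [-0.5, 0.5]]
    grid = build_box_grid(extents, spacing)
    eps = 1e-9
    channel_pos = np.array([[eps, eps, eps]])
    channel = ParticleSpec(
        name="channel", states=("closed", "open"), n=1,
        initial_state="closed", positions=channel_pos,
        transitions=[
            TransitionRule("closed", "open",
                           RateExpr(field="rho", coeff=alpha * beta,
                                    const=alpha * beta)),
            TransitionRule.constant("open", "closed", alpha)])
    field = FieldSpec("rho", D=d, initial=0.0, decay_rate=1.0,
                      decay_target=0.0)
    model = HybridModel(
        grid=grid, fields=[field], species=[channel],
        couplings=[FieldCoupling("rho", "channel", "open", a)],
        dt=dt, duration=duration, name="nondim-single-channel")
    return model


def build_nondim_line_model(alpha: float = 10.0, beta: float = 1.0,
                            a: float = 20.0 / 3.0, d: float = 1.0,
                            i_max: int = 2, dx: float = 2.0,
                            dt: float = 1e-4, duration: float = 1.0
                            ) -> HybridModel:
    """Quasi-1D nondimensional single-channel system on i_max subvolumes
    of size Δx; the spatial-discretization twin of
    :func:`hybridrd.reference.fp_functional_solve` (the channel source is
    a/Δx in node 0 on both sides of the comparison)."""
    grid = build_box_grid([[0.0, i_max * dx], [0.0, 1.0], [0.0, 1.0]],
                          (dx, 1.0, 1.0))
    channel = ParticleSpec(
        name="channel", states=("closed", "open"), n=1,
        initial_state="closed",
        positions=np.array([[dx / 2.0, 0.5, 0.5]]),
        transitions=[
            TransitionRule("closed", "open",
                           RateExpr(field="rho", coeff=alpha * beta,
                                    const=alpha * beta)),
            TransitionRule.constant("open", "closed", alpha)])
    field = FieldSpec("rho", D=d, initial=0.0, decay_rate=1.0,
                      decay_target=0.0)
    return HybridModel(
        grid=grid, fields=[field], species=[channel],
        couplings=[FieldCoupling("rho", "channel", "open", a)],
        dt=dt, duration=duration, name=f"nondim-line-{i_max}")


# ---------------------------------------------------------------------------
# stochastically gated reversible binding
# ---------------------------------------------------------------------------

class GatedParams:
    """Parameter identities of the gated-binding benchmark.

    All quantities derive from (L0, D, target κ_f·L0/κ_r ratio): the
    contact radius from κ_f = 4πD·r_c with κ_f·L0 = 0.3/τ_D, the
    diffusion time τ_D = r_c²/D, gating rates a = b = 1/τ_D, and the
    molar equivalent of the macromolecule count.
    """

    def __init__(self, L0_uM: float = 1.0, D: float = 1.0,
                 N: int = 20000, box: float = 10.0):
        self.L0_uM = L0_uM
        self.L0 = L0_uM * MOLECULES_PER_UM3            # μm⁻³
        self.D = D
        self.N = N
        self.box = box
        # r_c from the closure κ_f = 4πD r_c and κ_r = κ_f L0 = 0.3/τ_D
        self.r_c = (0.3 / (4.0 * math.pi * self.L0)) ** (1.0 / 3.0)  # μm
        self.tau_D = self.r_c ** 2 / D                                # s
        self.a = 1.0 / self.tau_D
        self.b = 1.0 / self.tau_D
        self.kappa_f = 4.0 * math.pi * D * self.r_c                   # μm³/s
        self.kappa_r = self.kappa_f * self.L0                         # s⁻¹
        self.volume = box ** 3
        self.N_uM = N / (self.volume * MOLECULES_PER_UM3)             # μM


def build_gated_model(params: Optional[GatedParams] = None,
                      box: float = 10.0, h: float = 0.2,
                      N: Optional[int] = None, dt: float = 1e-5,
                      duration: Optional[float] = None) -> HybridModel:
    """Gated reversible binding: immobile three-state macromolecules
    (inert ↔ active → complex → active) in a ligand bath held at L0 on
    the box boundary.

    The ligand field L is stored in μM; the per-particle binding rate
    κ_f·L(r,t) therefore uses the μM→μm⁻³ conversion inside the rate
    coefficient, and the ligand sink/source couplings carry the inverse
    conversion so that every term of the field equation is in μM/s.
    """
    if params is None:
        params = GatedParams(box=box)
    if N is None:
        # reference particle density: 20000 macromolecules per [0,10]³ box
        N = int(round(20000.0 * (box ** 3) / 1000.0))
    if duration is None:
        duration = 115.0 * params.tau_D
    kfdt = params.kappa_r * dt
    if kfdt >= 0.5:
        raise ValueError(f"κ_f·L0·Δt = {kfdt:.3g} ≥ 0.5 at build time; "
                         "reduce Δt")
    grid = build_box_grid([[0.0, box]] * 3, (h, h, h))
    # benchmark initial condition: unbound, equally partitioned between the
    # inert and reactive states (deterministic by particle index)
    init = np.zeros(N, dtype=np.int64)
    init[N // 2:] = 1
    macro = ParticleSpec(
        name="macro", states=("inert", "active", "complex"), n=N,
        initial_state=init, positions="uniform",
        transitions=[
            TransitionRule.constant("inert", "active", params.a),
            TransitionRule.constant("active", "inert", params.b),
            TransitionRule("active", "complex",
                           RateExpr(field="L",
                                    coeff=params.kappa_f
                                    * MOLECULES_PER_UM3)),
            TransitionRule.constant("complex", "active", params.kappa_r)])
    ligand = FieldSpec("L", D=params.D, bc="dirichlet",
                       bc_value=params.L0_uM, initial=params.L0_uM)
    model = HybridModel(
        grid=grid, fields=[ligand], species=[macro],
        couplings=[
            FieldCoupling("L", "macro", "active", -params.kappa_f,
                          kind="mass_action"),
            FieldCoupling("L", "macro", "complex",
                          params.kappa_r / MOLECULES_PER_UM3)],
        dt=dt, duration=duration, name="gated-binding")
    model.gated_params = params
    return model


# ---------------------------------------------------------------------------
# spontaneous cell polarization
# ---------------------------------------------------------------------------

class PolarityParams:
    """Defaults of the spontaneous-polarization benchmark (volume protein
    U, membrane-recruited protein S, two-state surface receptors with
    state-dependent mobility and a positive recruitment feedback)."""

    def __init__(self, R: float = 4.0, N_r: int = 1000, U0: float = 1.0,
                 D_U: float = 10.0, D_S: float = 0.1, D_G: float = 0.1,
                 k1: float = 0.01, k2: float = 0.01, k3: float = 0.01,
                 k4: float = 0.1, k0: float = 10.0, tau_p: float = 1.0):
        self.R, self.N_r, self.U0 = R, N_r, U0
        self.D_U, self.D_S, self.D_G = D_U, D_S, D_G
        # k3 multiplies the surface density S (μm⁻²); it is stored as the
        # per-rate coefficient with units μm²·s⁻¹ (the printed per-area
        # unit is dimensionally inconsistent with k3·S being a rate).
        self.k1, self.k2, self.k3, self.k4 = k1, k2, k3, k4
        self.k0, self.tau_p = k0, tau_p


def build_polarity_model(params: Optional[PolarityParams] = None,
                         grid_spacing: float = 0.5,
                         mesh_subdivisions: int = 3,
                         dt: float = 0.01, duration: float = 20.0,
                         pulse: bool = True) -> HybridModel:
    """Spontaneous polarization on a sphere of radius R.

    The volume is the pixelated interior of the sphere on a regular grid
    (cells whose centers fall inside); the membrane is a refined-
    icosahedron mesh.  Receptors live on the membrane: inactive receptors
    diffuse (D_Γ) and activate at rate k_3·S (+ optional pre-activation
    pulse k_0·e^(−t/τ)); active receptors are immobile, deactivate at
    k_4, and recruit cytosolic protein through the conservative membrane
    flux k_1·U·Γ − k_2·S.
    """
    if params is None:
        params = PolarityParams()
    R = params.R
    half = math.ceil(R / grid_spacing) * grid_spacing
    grid = build_box_grid([[-half, half]] * 3,
                          (grid_spacing,) * 3)
    grid = grid.with_mask(sphere_cell_mask(grid, R))
    mesh = icosphere(R, mesh_subdivisions)
    on = RateExpr(field="S", coeff=params.k3,
                  pulse_amp=params.k0 if pulse else 0.0,
                  pulse_tau=params.tau_p if pulse else None)
    receptors = ParticleSpec(
        name="receptors", states=("inactive", "active"), n=params.N_r,
        domain="surface", initial_state="inactive", positions="uniform",
        transitions=[TransitionRule("inactive", "active", on),
                     TransitionRule.constant("active", "inactive",
                                             params.k4)],
        mobility=MobilityRule({"inactive": params.D_G}))
    U = FieldSpec("U", D=params.D_U, initial=params.U0)
    S = FieldSpec("S", domain="surface", D=params.D_S, initial=0.0)
    model = HybridModel(
        grid=grid, fields=[U, S], species=[receptors],
        membrane=MembraneCoupling("U", "S", "receptors", "active",
                                  k_on=params.k1, k_off=params.k2),
        surface=mesh, dt=dt, duration=duration, name="polarity")
    model.polarity_params = params
    return model
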