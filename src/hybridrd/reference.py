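"""Independent oracles used to validate the hybrid engine.

* closed-form expectation of the spatially averaged concentration for the
  separable channel/release model;
* a Gibson-Bruck next-reaction simulator for well-mixed references
  (statistically exact in continuous time);
* direct Chapman-Kolmogorov / Fokker-Planck solvers for the
  nondimensionalized single-channel problem, in the fast-diffusion limit
  (one advection coordinate ρ) and at finite diffusion (one coordinate
  ρ_i per spatial node), with Richardson extrapolation in Δρ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# separable-model closed form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SparkParams:
    """Channel/release/pump parameters of the release-site testbed."""

    J: float = 10.0          # μM·μm³/s per open channel
    U0: float = 0.1          # μM
    k_on: float = 1.0        # s⁻¹
    k_off: float = 5.0       # s⁻¹
    V_p: float = 1.0         # s⁻¹
    D: float = 1.0           # μm²/s
    N_ch: int = 24
    volume: float = 10.1 * 2.1 * 0.5   # μm³


def open_probability(p: SparkParams, t) -> np.ndarray:
    """P(channel open at t | closed at 0) for constant rates."""
    lam = p.k_on + p.k_off
    pinf = p.k_on / lam
    return pinf * (-np.expm1(-lam * np.asarray(t, float)))


def analytic_mean_spark(p: SparkParams, t) -> np.ndarray:
    """Exact E[ spatial average of U at time t ] for the separable model.

    Channels start closed and U(r,0)=U0.  The spatial average obeys
    dŪ/dt = J·N_ch·p̄(t)/|Ω| − V_p(Ū−U0) with p̄ the mean open
    probability; integrating the linear ODE in closed form gives the
    value below.  Independent of D (spatial average of a linear system
    with no-flux boundaries).
    """
    t = np.asarray(t, dtype=float)
    lam = p.k_on + p.k_off
    pinf = p.k_on / lam
    c = p.J * p.N_ch / p.volume
    Vp = p.V_p
    if abs(Vp - lam) < 1e-12 * max(Vp, lam):
        # degenerate case: e^{-λt} term integrates to t·e^{-Vp t}
        conv = (-np.expm1(-Vp * t)) / Vp - t * np.exp(-Vp * t)
    else:
        conv = ((-np.expm1(-Vp * t)) / Vp
                - (np.exp(-lam * t) - np.exp(-Vp * t)) / (Vp - lam))
    return p.U0 + c * pinf * conv


# ---------------------------------------------------------------------------
# Gibson-Bruck next-reaction method
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """One reaction channel: propensity callback + integer stoichiometry.

    ``reads`` lists the species indices the propensity depends on; it
    feeds the next-reaction dependency graph (None = depends on all).
    """

    name: str
    propensity: Callable[[np.ndarray], float]
    delta: np.ndarray                    # change of copy numbers when fired
    reads: Optional[Tuple[int, ...]] = None


@dataclass
class WellMixedModel:
    """Well-mixed stochastic network in copy numbers."""

    species: Tuple[str, ...]
    initial: np.ndarray
    reactions: List[Reaction]
    volume: float = 1.0                  # μm³, for count↔concentration

    def index(self, name: str) -> int:
        return self.species.index(name)


def gibson_bruck_simulate(model: WellMixedModel, T: float,
                          rng: np.random.Generator,
                          record_times: Sequence[float] = ()
                          ) -> Dict[str, np.ndarray]:
    """Next-reaction simulation (Gibson-Bruck).

    Absolute next-firing times are stored per reaction; when a propensity
    changes from a_old to a_new without the reaction firing, the unfired
    time is reused as t + (a_old/a_new)·(t_next − t); the fired reaction
    redraws an exponential.  With the handful of reaction channels used by
    the reference models the priority structure is a plain argmin.
    Returns the copy-number snapshots at ``record_times`` plus the final
    state and the event count.
    """
    x = np.asarray(model.initial, dtype=np.int64).copy()
    reactions = model.reactions
    n_r = len(reactions)
    # dependency graph: reactions whose propensity reads a species changed
    # by the firing reaction (the fired reaction itself is always updated)
    changed = [tuple(np.flatnonzero(r.delta)) for r in reactions]
    reads = [tuple(range(len(x))) if r.reads is None else tuple(r.reads)
             for r in reactions]
    affected = [tuple(k for k in range(n_r)
                      if k != mu and set(reads[k]) & set(changed[mu]))
                for mu in range(n_r)]
    props = [r.propensity for r in reactions]
    deltas = [r.delta for r in reactions]
    expo = rng.exponential
    a = [max(props[k](x), 0.0) for k in range(n_r)]
    tau = [(expo(1.0) / a[k] if a[k] > 0 else math.inf) for k in range(n_r)]
    record_times = np.asarray(record_times, dtype=float)
    out = np.empty((len(record_times), len(x)), dtype=np.int64)
    rec_ptr = 0
    t = 0.0
    events = 0
    rng_idx = range(n_r)
    while True:
        mu = min(rng_idx, key=tau.__getitem__)
        t_next = tau[mu]
        while rec_ptr < len(record_times) and record_times[rec_ptr] <= \
                min(t_next, T):
            out[rec_ptr] = x
            rec_ptr += 1
        if t_next > T or not math.isfinite(t_next):
            break
        t = t_next
        x += deltas[mu]
        events += 1
        a_mu = max(props[mu](x), 0.0)
        tau[mu] = t + expo(1.0) / a_mu if a_mu > 0 else math.inf
        a[mu] = a_mu
        for k in affected[mu]:
            a_new = max(props[k](x), 0.0)
            if a_new == a[k]:
                continue
            if a_new <= 0:
                tau[k] = math.inf
            elif math.isfinite(tau[k]):
                # absolute-time reuse of the unfired reaction time
                tau[k] = t + (a[k] / a_new) * (tau[k] - t)
            else:
                tau[k] = t + expo(1.0) / a_new
            a[k] = a_new
    while rec_ptr < len(record_times):
        out[rec_ptr] = x
        rec_ptr += 1
    return {"times": record_times, "counts": out, "final": x,
            "events": events}


def spark_well_mixed(p: SparkParams, coupled: bool = True,
                     molecules_per_um3: float = 602.0) -> WellMixedModel:
    """Fully stochastic well-mixed version of the release-site model.

    Calcium becomes a copy number N_U (U = N_U / (c·|Ω|) μM with
    c = molecules/μm³ at 1 μM); channel opening uses k_on·U/U_0 when
    ``coupled``.  Reactions: opening, closing, influx J per open channel,
    baseline production V_p·U0 and first-order removal V_p per molecule.
    """
    conv = molecules_per_um3 * p.volume          # molecules per μM
    n_u0 = p.U0 * conv
    j_count = p.J * molecules_per_um3            # molecules/s per open channel

    def a_open(x):
        if coupled:
            return p.k_on * (x[1] / n_u0) * x[2]
        return p.k_on * x[2]

    open_reads = (0, 1, 2) if coupled else (2,)
    reactions = [
        Reaction("open", a_open, np.array([1, 0, -1]), open_reads),
        Reaction("close", lambda x: p.k_off * x[0], np.array([-1, 0, 1]),
                 (0,)),
        Reaction("influx", lambda x: j_count * x[0], np.array([0, 1, 0]),
                 (0,)),
        Reaction("production", lambda x: p.V_p * n_u0, np.array([0, 1, 0]),
                 ()),
        Reaction("removal", lambda x: p.V_p * x[1], np.array([0, -1, 0]),
                 (1,)),
    ]
    initial = np.array([0, int(round(n_u0)), p.N_ch], dtype=np.int64)
    return WellMixedModel(("open", "N_U", "closed"), initial, reactions,
                          p.volume)


# ---------------------------------------------------------------------------
# Fokker-Planck solvers (nondimensional single-channel problem)
# ---------------------------------------------------------------------------

@dataclass
class FPGridSolution:
    """Two-component probability density on a ρ grid.

    For the fast-diffusion limit the grid is one-dimensional in ρ; for the
    finite-diffusion functional equation there is one ρ-axis per spatial
    node.  ``p0``/``p1`` are cell-centered densities; the cell measure is
    the product of the Δρ_i.
    """

    edges: List[np.ndarray]
    p0: np.ndarray
    p1: np.ndarray
    tau: float
    params: dict = field(default_factory=dict)

    @property
    def centers(self) -> List[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def cell_measure(self) -> float:
        return float(np.prod([e[1] - e[0] for e in self.edges]))

    def total_probability(self) -> float:
        return float((self.p0 + self.p1).sum() * self.cell_measure)

    def marginal(self, axis: int = 0) -> np.ndarray:
        """Density of ρ_axis, integrating out the other coordinates and
        summing the channel states."""
        p = self.p0 + self.p1
        other = tuple(i for i in range(p.ndim) if i != axis)
        meas = self.cell_measure / (self.edges[axis][1]
                                    - self.edges[axis][0])
        return p.sum(axis=other) * meas

    def mean_rho(self, axis: int = 0) -> float:
        m = self.marginal(axis)
        c = self.centers[axis]
        d = self.edges[axis][1] - self.edges[axis][0]
        return float((m * c).sum() * d)

    def open_probability(self) -> float:
        return float(self.p1.sum() * self.cell_measure)


def _upwind_flux_1d(p: np.ndarray, drift_edges: np.ndarray) -> np.ndarray:
    """Donor-cell flux at interior edges; zero flux at the boundaries."""
    flux = np.zeros(len(p) + 1)
    v = drift_edges
    flux[1:-1] = np.where(v[1:-1] > 0, v[1:-1] * p[:-1], v[1:-1] * p[1:])
    return flux


def fp_fast_solve(alpha: float, beta: float, a: float,
                  rho_max: Optional[float] = None, n_rho: int = 240,
                  tau_end: float = 30.0, cfl: float = 0.5,
                  save_times: Sequence[float] = ()) -> FPGridSolution:
    """Fast-diffusion-limit Chapman-Kolmogorov solve.

    Two density components advect with drifts −ρ (closed) and a−ρ (open)
    and exchange at rates αβ(ρ+1) (opening) and α (closing); donor-cell
    upwind transport, explicit Euler in τ at the given CFL number.  The
    initial condition is all mass closed at ρ=0.
    """
    if rho_max is None:
        rho_max = 1.2 * a
    if rho_max < a:
        raise ValueError("rho_max must cover the open-state fixed point a")
    edges = np.linspace(0.0, rho_max, n_rho + 1)
    d_rho = edges[1] - edges[0]
    centers = 0.5 * (edges[1:] + edges[:-1])
    p0 = np.zeros(n_rho)
    p1 = np.zeros(n_rho)
    p0[0] = 1.0 / d_rho                     # δ(ρ) in the first cell
    v0 = -edges                              # drift of the closed component
    v1 = a - edges
    vmax = max(np.abs(v0).max(), np.abs(v1).max())
    d_tau = cfl * d_rho / vmax
    n_steps = int(math.ceil(tau_end / d_tau))
    d_tau = tau_end / n_steps
    if vmax * d_tau / d_rho > 1.0:
        raise ValueError("CFL violation")
    for _ in range(n_steps):
        R = alpha * (p1 - beta * (centers + 1.0) * p0)
        f0 = _upwind_flux_1d(p0, v0)
        f1 = _upwind_flux_1d(p1, v1)
        p0 = p0 - d_tau * np.diff(f0) / d_rho + d_tau * R
        p1 = p1 - d_tau * np.diff(f1) / d_rho - d_tau * R
    return FPGridSolution([edges], p0, p1, tau_end,
                          {"alpha": alpha, "beta": beta, "a": a})


def fp_functional_solve(alpha: float, beta: float, a: float, d: float,
                        i_max: int, dx: float,
                        rho_max: Optional[Sequence[float]] = None,
                        n_rho: Optional[Sequence[int]] = None,
                        d_rho: Optional[float] = None,
                        tau_end: float = 1.0, cfl: float = 0.5,
                        memory_cap: float = 2e8) -> FPGridSolution:
    """Finite-diffusion functional Fokker-Planck solve on a coarse grid.

    Each spatial node i of the discretized field contributes one advection
    coordinate ρ_i with drift

        b_i = d·(Lρ)_i − ρ_i + (a/Δx)·δ_{i,0}·ξ,

    where L is the reflecting discrete Laplacian in x and the point source
    is discretized as a/Δx in node 0 — exactly mirroring the hybrid
    engine's subvolume binning, so both sides of a comparison share one
    spatial discretization.  Two components (channel closed/open) exchange
    through R = α(p1 − β(ρ_0+1)p0).  Dimensional donor-cell transport,
    explicit Euler at the given CFL number; no-flux boundaries in every
    ρ_i.  Total probability is conserved to solver accuracy.
    """
    if i_max not in (2, 3):
        raise ValueError("i_max must be 2 or 3 (memory-feasible grids)")
    if rho_max is None:
        rho_max = default_rho_max(a, d, i_max, dx)
    rho_max = list(map(float, rho_max))
    if n_rho is None:
        if d_rho is None:
            raise ValueError("give either n_rho or d_rho")
        n_rho = [int(round(r / d_rho)) for r in rho_max]
        rho_max = [n * d_rho for n in n_rho]
    cells = int(np.prod(n_rho))
    if 2 * cells * 8 * 4 > memory_cap:
        raise MemoryError(f"FP grid of {cells} cells exceeds the memory "
                          "cap; coarsen Δρ")
    edges = [np.linspace(0.0, rho_max[i], n_rho[i] + 1)
             for i in range(i_max)]
    d_rhos = [e[1] - e[0] for e in edges]
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    shape = tuple(n_rho)
    p0 = np.zeros(shape)
    p1 = np.zeros(shape)
    p0[(0,) * i_max] = 1.0 / np.prod(d_rhos)
    # coordinate grids broadcast along their own axis
    def ax_view(arr, i):
        sh = [1] * i_max
        sh[i] = -1
        return arr.reshape(sh)

    # drift along axis i evaluated at the *edges* of axis i, centers elsewhere
    lap_coeff = d / dx ** 2
    source0 = a / dx

    def drift(i, xi_open):
        # d·(Lρ)_i − ρ_i + (a/Δx)·δ_{i0}·ξ with ρ_i at edge positions
        e = ax_view(edges[i], i)
        # neighbor terms use cell-center values of the other coordinates
        if i_max == 2:
            other = centers[1 - i]
            nb = ax_view(other, 1 - i)
            lap = lap_coeff * (nb - e)
        else:
            if i == 0:
                nb = ax_view(centers[1], 1)
                lap = lap_coeff * (nb - e)
            elif i == 1:
                lap = lap_coeff * (ax_view(centers[0], 0) - e) \
                    + lap_coeff * (ax_view(centers[2], 2) - e)
            else:
                lap = lap_coeff * (ax_view(centers[1], 1) - e)
        b = lap - e
        if i == 0 and xi_open:
            b = b + source0
        return b

    # CFL bound from the maximal possible drift magnitudes
    vmax = []
    for i in range(i_max):
        hi = max(abs(drift(i, True)).max(), abs(drift(i, False)).max())
        vmax.append(hi / d_rhos[i])
    d_tau = cfl / sum(vmax)
    n_steps = int(math.ceil(tau_end / d_tau))
    d_tau = tau_end / n_steps

    rho0 = ax_view(centers[0], 0)
    for _ in range(n_steps):
        R = alpha * (p1 - beta * (rho0 + 1.0) * p0)
        new0 = p0 + d_tau * R
        new1 = p1 - d_tau * R
        for i in range(i_max):
            for comp, (pold, pnew) in enumerate(((p0, new0), (p1, new1))):
                v = drift(i, bool(comp))
                vb = np.broadcast_to(v, _edge_shape(shape, i)).copy()
                # zero boundary fluxes
                sl_lo = [slice(None)] * i_max
                sl_lo[i] = 0
                vb[tuple(sl_lo)] = 0.0
                sl_hi = [slice(None)] * i_max
                sl_hi[i] = -1
                vb[tuple(sl_hi)] = 0.0
                up = np.where(vb[_int_slice(shape, i)] > 0,
                              _shift_view(pold, i, "lo"),
                              _shift_view(pold, i, "hi"))
                flux = vb[_int_slice(shape, i)] * up
                # divergence F_hi − F_lo per cell
                dflx = np.zeros(shape)
                dflx[_cell_slice(shape, i, "hi")] += flux   # hi edge of k
                dflx[_cell_slice(shape, i, "lo")] -= flux   # lo edge of k
                pnew -= d_tau * dflx / d_rhos[i]
        p0, p1 = new0, new1
    return FPGridSolution(edges, p0, p1, tau_end,
                          {"alpha": alpha, "beta": beta, "a": a, "d": d,
                           "dx": dx, "i_max": i_max})


def default_rho_max(a: float, d: float, i_max: int, dx: float,
                    margin: float = 1.2) -> List[float]:
    """ρ ranges from the all-open steady state of the binned deterministic
    system, times a safety margin (the drift field keeps the box
    invariant)."""
    L = np.zeros((i_max, i_max))
    for i in range(i_max):
        if i > 0:
            L[i, i - 1] += d / dx ** 2
            L[i, i] -= d / dx ** 2
        if i < i_max - 1:
            L[i, i + 1] += d / dx ** 2
            L[i, i] -= d / dx ** 2
    b = np.zeros(i_max)
    b[0] = a / dx
    rho_ss = np.linalg.solve(np.eye(i_max) - L, b)
    return [margin * float(r) for r in rho_ss]


def _edge_shape(shape, i):
    s = list(shape)
    s[i] += 1
    return tuple(s)


def _int_slice(shape, i):
    sl = [slice(None)] * len(shape)
    sl[i] = slice(1, shape[i])
    return tuple(sl)


def _shift_view(p, i, side):
    sl = [slice(None)] * p.ndim
    sl[i] = slice(0, -1) if side == "lo" else slice(1, None)
    return p[tuple(sl)]


def _cell_slice(shape, i, side):
    sl = [slice(None)] * len(shape)
    sl[i] = slice(1, None) if side == "lo" else slice(0, -1)
    return tuple(sl)


# ---------------------------------------------------------------------------
# Richardson extrapolation
# ---------------------------------------------------------------------------

def richardson_extrapolate(values: Sequence[float],
                           steps: Sequence[float]
                           ) -> Tuple[float, np.ndarray]:
    """Extrapolate grid-refined values to zero step size.

    Least-squares polynomial fit in Δρ of order min(2, n−1); returns the
    constant term and the fit residuals.
    """
    values = np.asarray(values, float)
    steps = np.asarray(steps, float)
    if len(values) != len(steps) or len(values) < 2:
        raise ValueError("need at least two (value, step) pairs")
    if np.any(np.diff(steps) >= 0):
        raise ValueError("steps must be strictly decreasing")
    order = min(2, len(values) - 1)
    coeffs = np.polynomial.polynomial.polyfit(steps, values, order)
    resid = values - np.polynomial.polynomial.polyval(steps, coeffs)
    return float(coeffs[0]), resid
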