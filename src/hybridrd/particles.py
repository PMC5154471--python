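"""Fixed-time-step particle engine.

State transitions use acceptance-rejection sampling with the exact one-step
waiting probability at frozen rates: a particle with total outgoing rate k
leaves its state during Δt with probability 1 − exp(−k·Δt); when several
destinations are possible the single uniform draw is partitioned
proportionally to the individual rates.  At most one transition occurs per
particle per step, which requires k·Δt small; a runtime guard enforces
k·Δt < 0.5 (configurable) and raises rather than silently losing accuracy.

Mobile particles take Gaussian steps with per-axis variance 2·D·Δt
(the exact free-diffusion propagator), reflected at box walls; surface
particles take a tangent-plane step and are reprojected onto the mesh.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .geometry import (ParticleSet, SpatialGrid, SurfaceMesh, locate_cells)

#: default guard on (total outgoing rate)·Δt
RATE_DT_GUARD = 0.5


@dataclass(frozen=True)
class RateExpr:
    """Transition rate: ``const + coeff·field(r,t) + pulse_amp·exp(−t/pulse_tau)``.

    ``field`` names a model field evaluated in the particle's containing
    subvolume (volume fields, μM) or surface element (surface fields,
    μm⁻²); ``None`` means a constant rate.  All terms are in s⁻¹ after the
    multiplication, e.g. the fully coupled channel opening rate
    k_on·U/U_0 is ``RateExpr(field="U", coeff=k_on/U_0)`` and the
    pre-activation pulse k_0·e^(−t/τ)+k_3·S is
    ``RateExpr(field="S", coeff=k_3, pulse_amp=k_0, pulse_tau=τ)``.
    """

    field: Optional[str] = None
    coeff: float = 0.0
    const: float = 0.0
    pulse_amp: float = 0.0
    pulse_tau: Optional[float] = None

    def __post_init__(self):
        if self.pulse_amp and (self.pulse_tau is None or self.pulse_tau <= 0):
            raise ValueError("pulse declared with non-positive time constant")

    def evaluate(self, field_at_particle, t: float):
        """Per-particle rate values (s⁻¹); clamps negative field inputs."""
        r = self.const
        if self.pulse_amp:
            r = r + self.pulse_amp * math.exp(-t / self.pulse_tau)
        if self.field is not None:
            f = field_at_particle
            if np.any(f < 0):
                warnings.warn(
                    f"negative field value fed to rate on {self.field!r}; "
                    "clamped to 0", RuntimeWarning, stacklevel=2)
                f = np.maximum(f, 0.0)
            r = r + self.coeff * f
        return r


@dataclass(frozen=True)
class TransitionRule:
    """Markov transition (from_state → to_state) at the given rate."""

    from_state: str
    to_state: str
    rate: RateExpr

    @staticmethod
    def constant(from_state: str, to_state: str, k: float) -> "TransitionRule":
        return TransitionRule(from_state, to_state, RateExpr(const=k))


@dataclass(frozen=True)
class MobilityRule:
    """Per-state diffusivities (μm²/s). States not listed are immobile."""

    diffusivity: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(d < 0 for d in self.diffusivity.values()):
            raise ValueError("diffusivity must be non-negative")

    @property
    def is_immobile(self) -> bool:
        return all(d == 0 for d in self.diffusivity.values())


def evaluate_rates(particles: ParticleSet, rules: Sequence[TransitionRule],
                   fields_at_particles: Dict[str, np.ndarray], t: float
                   ) -> np.ndarray:
    """Rate matrix (n_particles, n_rules); zero where a rule does not apply.

    ``fields_at_particles`` carries, per field name, the field value in
    each particle's containing subvolume/element (piecewise-constant field
    evaluation; no interpolation).
    """
    n = particles.n
    rates = np.zeros((n, len(rules)))
    for k, rule in enumerate(rules):
        sel = particles.state == particles.state_code(rule.from_state)
        if not sel.any():
            continue
        fvals = None
        if rule.rate.field is not None:
            fvals = fields_at_particles[rule.rate.field][sel]
        r = rule.rate.evaluate(fvals, t)
        rates[sel, k] = r
        if np.any(rates[sel, k] < 0):
            raise ValueError(f"negative rate from rule "
                             f"{rule.from_state}->{rule.to_state}")
    return rates


def sample_transitions(particles: ParticleSet,
                       rules: Sequence[TransitionRule],
                       rates: np.ndarray, dt: float,
                       uniforms: np.ndarray,
                       guard: float = RATE_DT_GUARD) -> None:
    """In-place acceptance-rejection state update (one uniform per particle).

    ``rates`` is the (n, n_rules) matrix from :func:`evaluate_rates`,
    evaluated from the time-t fields.  A particle transitions with
    probability 1 − exp(−k_tot·Δt); the destination is chosen by
    partitioning the accepted uniform proportionally to individual rates.
    """
    ktot = rates.sum(axis=1)
    worst = ktot.max(initial=0.0) * dt
    if worst >= guard:
        k = int(np.argmax(rates.sum(axis=1)))
        j = int(np.argmax(rates[k]))
        rule = rules[j]
        raise ValueError(
            f"rate·Δt = {worst:.3g} ≥ {guard} for species "
            f"{particles.species!r} (worst rule "
            f"{rule.from_state}->{rule.to_state}); reduce Δt")
    p = -np.expm1(-ktot * dt)
    accept = uniforms < p
    if not accept.any():
        return
    # partition the accepted uniform over destinations
    frac = np.zeros_like(uniforms)
    frac[accept] = uniforms[accept] / p[accept]
    cum = np.cumsum(rates[accept], axis=1)
    cum /= cum[:, -1][:, None]
    dest_rule = (frac[accept][:, None] >= cum).sum(axis=1)
    dest_rule = np.minimum(dest_rule, rates.shape[1] - 1)
    to_codes = np.array([particles.state_code(r.to_state) for r in rules])
    particles.state[accept] = to_codes[dest_rule]


def diffuse_volume(particles: ParticleSet, mobility: MobilityRule,
                   grid: SpatialGrid, dt: float, normals: np.ndarray,
                   max_reflections: int = 100) -> None:
    """Reflecting Brownian step for mobile volume particles (in place).

    ``normals`` is an (n, 3) standard-normal block drawn from the
    realization's stream (always full shape, so the draw count per step is
    state-independent and streams stay reproducible).
    """
    if mobility.is_immobile:
        return
    sigma = np.zeros(particles.n)
    for label, D in mobility.diffusivity.items():
        if D > 0:
            sel = particles.state == particles.state_code(label)
            sigma[sel] = math.sqrt(2.0 * D * dt)
    if not sigma.any():
        return
    pos = particles.positions + sigma[:, None] * normals
    lo, hi = grid.lo, grid.hi
    span = hi - lo
    for _ in range(max_reflections):
        below = pos < lo
        above = pos > hi
        if not (below.any() or above.any()):
            break
        pos = np.where(below, 2 * lo - pos, pos)
        pos = np.where(above, 2 * hi - pos, pos)
    else:
        raise RuntimeError("particle escaped geometry after reflection cap "
                           "(Δt too large for this domain)")
    particles.positions = pos


def diffuse_surface(particles: ParticleSet, mobility: MobilityRule,
                    mesh: SurfaceMesh, dt: float,
                    normals: np.ndarray) -> None:
    """Tangent-plane Gaussian step + reprojection for surface particles.

    Mobile particles move by an isotropic 2D Gaussian step (variance
    2·D·Δt per tangent axis) in the plane of their current element and are
    then reprojected to the nearest point on the mesh, stored again as
    exact (triangle, barycentric) coordinates.  Immobile-state particles
    (e.g. active receptors) never move.
    """
    if mobility.is_immobile:
        return
    sigma = np.zeros(particles.n)
    for label, D in mobility.diffusivity.items():
        if D > 0:
            sel = particles.state == particles.state_code(label)
            sigma[sel] = math.sqrt(2.0 * D * dt)
    mobile = sigma > 0
    if not mobile.any():
        return
    step_rms = float(np.max(sigma)) * math.sqrt(2.0)
    med_edge = math.sqrt(float(np.median(mesh.areas)) * 2.0)
    if step_rms > med_edge:
        warnings.warn("surface diffusion step exceeds the local edge "
                      "length; reduce Δt or refine the mesh",
                      RuntimeWarning, stacklevel=2)
    pos = particles.cartesian(mesh)
    n = mesh.normals[particles.tri]
    # orthonormal tangent basis per particle
    ref = np.where(np.abs(n[:, [0]]) < 0.9,
                   np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    t1 = np.cross(n, ref)
    t1 /= np.linalg.norm(t1, axis=1)[:, None]
    t2 = np.cross(n, t1)
    newpos = (pos + sigma[:, None] * (normals[:, [0]] * t1
                                      + normals[:, [1]] * t2))
    tri, bary = mesh.locate(newpos[mobile])
    particles.tri[mobile] = tri
    particles.bary[mobile] = bary


def field_values_at_particles(particles: ParticleSet,
                              fields: Dict[str, np.ndarray],
                              grid: Optional[SpatialGrid],
                              which: Sequence[str],
                              surface_fields: Sequence[str] = ()
                              ) -> Dict[str, np.ndarray]:
    """Field value in each particle's containing subvolume / element."""
    out = {}
    cells = None
    for name in which:
        if name in surface_fields or particles.domain == "surface":
            out[name] = fields[name][particles.tri]
        else:
            if cells is None:
                cells = locate_cells(grid, particles.positions)
            out[name] = fields[name][cells]
    return out
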