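"""Finite-volume semi-implicit integrator for the continuous subsystem.

The diffusion (and, on surfaces, Laplace-Beltrami) operator is applied to
the field at time t+Δt while reaction and membrane-flux terms are evaluated
from the state at time t:

    (I − Δt·D·L)·U(t+Δt) = U(t) + Δt·(sources at t).

With no-flux boundaries the discrete diffusion operator has zero row sums
(an M-matrix structure), so total mass ``Σ_j U_j |ω_j|`` is conserved to
linear-solver tolerance for arbitrarily many steps, and the scheme is
unconditionally stable in Δt.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SpatialGrid, SurfaceMesh

#: switch from direct sparse factorization to preconditioned CG above this size
_DIRECT_SOLVE_MAX_CELLS = 100_000
#: below this size a dense inverse is cheaper than repeated sparse solves
_DENSE_SOLVE_MAX_CELLS = 300
_CG_RTOL = 1e-10


class DiffusionOperator:
    """Discrete diffusion operator D·L on a box grid (optionally masked).

    Parameters
    ----------
    grid : SpatialGrid
    D : diffusivity in μm²/s (D = 0 yields the identity step).
    bc : "no-flux" or "dirichlet".  Dirichlet fixes the field value on the
        *outer box boundary* to ``dirichlet_value`` via ghost cells.
    """

    def __init__(self, grid: SpatialGrid, D: float, bc: str = "no-flux",
                 dirichlet_value: float = 0.0):
        if D < 0:
            raise ValueError("diffusivity must be non-negative")
        if bc not in ("no-flux", "dirichlet"):
            raise ValueError(f"unsupported boundary condition {bc!r}")
        self.grid = grid
        self.D = float(D)
        self.bc = bc
        self.dirichlet_value = float(dirichlet_value)
        self.L, self.bc_rhs = self._assemble()
        self._factor_cache: dict = {}

    def _assemble(self):
        g = self.grid
        n = g.n_cells
        nx, ny, nz = (int(s) for s in g.shape)
        active = np.ones(n, bool) if g.mask is None else g.mask
        j = np.arange(n)
        ix, iy, iz = g.axis_indices(j)
        diag = np.zeros(n)
        rows, cols, vals = [], [], []
        bc_rhs = np.zeros(n)
        strides = (1, nx, nx * ny)
        axidx = (ix, iy, iz)
        dims = (nx, ny, nz)
        for a in range(3):
            w = self.D / g.spacing[a] ** 2
            if w == 0.0:
                continue
            if dims[a] > 1:
                # interior faces: neighbor at +1 along axis a
                has_nb = axidx[a] < dims[a] - 1
                jj = j[has_nb]
                kk = jj + strides[a]
                both = active[jj] & active[kk]
                jj, kk = jj[both], kk[both]
                rows += [jj, kk]
                cols += [kk, jj]
                vals += [np.full(len(jj), w), np.full(len(kk), w)]
                np.add.at(diag, jj, -w)
                np.add.at(diag, kk, -w)
            if self.bc == "dirichlet":
                # ghost-cell closure: boundary face flux 2w(U_bc − U)
                for side_idx in (axidx[a] == 0, axidx[a] == dims[a] - 1):
                    bj = j[side_idx & active]
                    diag[bj] += -2.0 * w
                    bc_rhs[bj] += 2.0 * w * self.dirichlet_value
        rows.append(j)
        cols.append(j)
        vals.append(diag)
        L = sp.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
        if g.mask is not None:
            keep = sp.diags(active.astype(float))
            L = keep @ L @ keep
            bc_rhs *= active
        return L, bc_rhs

    def step_matrix(self, dt: float):
        """Cached solver for (I − Δt·D·L)."""
        key = float(dt)
        if key not in self._factor_cache:
            n = self.grid.n_cells
            A = sp.eye(n, format="csc") - dt * self.L.tocsc()
            if n <= _DENSE_SOLVE_MAX_CELLS:
                # small well-conditioned M-matrix: one dense inverse, then
                # each step is a BLAS-3 multiply (fast for many columns)
                inv = np.linalg.inv(A.toarray())
                self._factor_cache[key] = ("dense", A, inv)
            elif n <= _DIRECT_SOLVE_MAX_CELLS:
                lu = spla.splu(A)
                self._factor_cache[key] = ("direct", A, lu)
            else:
                ilu = spla.spilu(A, drop_tol=1e-5)
                M = spla.LinearOperator((n, n), ilu.solve)
                self._factor_cache[key] = ("cg", A, M)
        return self._factor_cache[key]


def assemble_diffusion_operator(grid: SpatialGrid, D: float,
                                bc: str = "no-flux",
                                dirichlet_value: float = 0.0
                                ) -> DiffusionOperator:
    return DiffusionOperator(grid, D, bc, dirichlet_value)


def semi_implicit_step(values: np.ndarray, op: DiffusionOperator,
                       sources: Optional[np.ndarray], dt: float
                       ) -> np.ndarray:
    """One semi-implicit update; ``values`` may be (n,) or (n, n_real).

    ``sources`` are per-cell explicit rates (μM/s) evaluated at time t and
    must already include any reaction, decay, particle-source and boundary
    flux terms. Dirichlet boundary forcing is added automatically.
    """
    rhs = values + (0.0 if sources is None else dt * sources)
    if op.bc_rhs.any():
        rhs = rhs + (dt * op.bc_rhs if rhs.ndim == 1
                     else dt * op.bc_rhs[:, None])
    kind, A, solver = op.step_matrix(dt)
    if kind == "dense":
        out = solver @ rhs
    elif kind == "direct":
        out = solver.solve(rhs)
    else:
        if rhs.ndim == 1:
            out, info = spla.cg(A, rhs, rtol=_CG_RTOL, M=solver)
            if info != 0:
                raise RuntimeError(f"CG failed to converge (info={info})")
        else:
            out = np.empty_like(rhs)
            for c in range(rhs.shape[1]):
                out[:, c], info = spla.cg(A, rhs[:, c], rtol=_CG_RTOL,
                                          M=solver)
                if info != 0:
                    raise RuntimeError(f"CG failed to converge (info={info})")
        resid = np.linalg.norm(A @ out - rhs) \
            / max(np.linalg.norm(rhs), 1e-300)
        if resid > 1e-8:
            raise RuntimeError(f"linear solve residual {resid:.2e} above "
                               "tolerance")
    return out


# ---------------------------------------------------------------------------
# surface diffusion
# ---------------------------------------------------------------------------

class SurfaceOperator:
    """Finite-volume Laplace-Beltrami operator on triangle elements.

    The unknowns are per-element surface densities. Transport between two
    elements sharing an edge uses the two-point flux w_e = |edge| / d_cc,
    where d_cc is the centroid-to-centroid distance; the flux form makes
    total surface mass ``Σ_e S_e·area_e`` conserved by construction (row
    sums of A·L vanish).
    """

    def __init__(self, mesh: SurfaceMesh, D: float):
        if D < 0:
            raise ValueError("diffusivity must be non-negative")
        self.mesh = mesh
        self.D = float(D)
        self.L = self._assemble()
        self._factor_cache: dict = {}

    def _assemble(self):
        mesh = self.mesh
        tris = mesh.triangles
        edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                                tris[:, [2, 0]]])
        owner = np.tile(np.arange(len(tris)), 3)
        key = np.sort(edges, axis=1)
        order = np.lexsort((key[:, 1], key[:, 0]))
        key, owner, edges = key[order], owner[order], edges[order]
        # closed surface: consecutive pairs share an edge
        fa, fb = owner[0::2], owner[1::2]
        ea = key[0::2]
        elen = np.linalg.norm(mesh.vertices[ea[:, 0]]
                              - mesh.vertices[ea[:, 1]], axis=1)
        dcc = np.linalg.norm(mesh.centroids[fa] - mesh.centroids[fb], axis=1)
        w = self.D * elen / dcc                     # μm²/s · dimensionless
        n = mesh.n_elements
        # dS_a/dt = Σ_edges w(S_b − S_a)/area_a
        rows = np.concatenate([fa, fb, fa, fb])
        cols = np.concatenate([fb, fa, fa, fb])
        vals = np.concatenate([w / mesh.areas[fa], w / mesh.areas[fb],
                               -w / mesh.areas[fa], -w / mesh.areas[fb]])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def step_matrix(self, dt: float):
        key = float(dt)
        if key not in self._factor_cache:
            A = sp.eye(self.mesh.n_elements, format="csc") - dt * self.L
            self._factor_cache[key] = (A, spla.splu(A.tocsc()))
        return self._factor_cache[key]


def surface_step(values: np.ndarray, op: SurfaceOperator,
                 sources: Optional[np.ndarray], dt: float) -> np.ndarray:
    """Semi-implicit Laplace-Beltrami update of a surface density field."""
    rhs = values + (0.0 if sources is None else dt * sources)
    A, lu = op.step_matrix(dt)
    out = lu.solve(np.ascontiguousarray(rhs))
    return out


# ---------------------------------------------------------------------------
# membrane flux coupling
# ---------------------------------------------------------------------------

def map_elements_to_cells(mesh: SurfaceMesh, grid: SpatialGrid) -> np.ndarray:
    """Adjacent boundary subvolume for every surface element.

    Each element is mapped to the active grid cell containing (or nearest
    along the inward normal to) its centroid; used to exchange mass between
    the volume field and the surface field.
    """
    from .geometry import locate_cells
    pts = mesh.centroids - 0.51 * np.min(grid.spacing) * mesh.normals
    pts = np.clip(pts, grid.lo + 1e-12, grid.hi - 1e-12)
    cells = locate_cells(grid, pts)
    if grid.mask is not None:
        bad = ~grid.mask[cells]
        if bad.any():
            # walk further inward until an active cell is found
            for step in (1.0, 1.6, 2.4):
                pts2 = (mesh.centroids[bad]
                        - step * np.max(grid.spacing) * mesh.normals[bad])
                pts2 = np.clip(pts2, grid.lo + 1e-12, grid.hi - 1e-12)
                cells[bad] = locate_cells(grid, pts2)
                bad = ~grid.mask[cells]
                if not bad.any():
                    break
            if bad.any():
                raise ValueError("surface element with no adjacent active "
                                 "boundary cell (meshing error)")
    return cells


def exchange_membrane_flux(flux_per_area: np.ndarray, elem_to_cell: np.ndarray,
                           areas: np.ndarray, grid: SpatialGrid,
                           molecules_per_um3: float):
    """Convert a per-element molecular flux into paired field sources.

    ``flux_per_area`` is in molecules/(μm²·s), positive toward the surface.
    Returns (volume source in μM/s per cell, surface source in μm⁻²/s per
    element); the molecule bookkeeping of the two returned terms is equal
    and opposite per element — the local mass-conservation contract.
    """
    surf_src = flux_per_area
    vol_src = np.zeros(grid.n_cells)
    np.add.at(vol_src, elem_to_cell, -flux_per_area * areas)
    vol_src /= (grid.cell_volume * molecules_per_um3)
    return vol_src, surf_src


def warn_if_negative(values: np.ndarray, name: str) -> None:
    """Negative concentrations from explicit sinks are reported, not clipped
    (clipping would silently break conservation)."""
    if np.any(values < 0):
        warnings.warn(f"field {name!r} went negative "
                      f"(min {float(np.min(values)):.3e}); explicit sink "
                      "terms may need a smaller Δt", RuntimeWarning,
                      stacklevel=2)
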