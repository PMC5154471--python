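"""Volume grids, triangulated closed surfaces, and particle containers.

Conventions used package-wide
-----------------------------
* Units: lengths in μm, areas in μm², volumes in μm³, time in s,
  volume concentrations in μM, surface densities in molecules/μm².
  ``MOLECULES_PER_UM3`` converts 1 μM into a number density.
* Cell indexing of a box grid is lexicographic with x fastest:
  ``j = ix + nx*(iy + ny*iz)``.
* Cells are half-open, ``[low, high)`` on every axis; the global upper
  boundary of the box is closed so every point of the closed box maps to
  exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

#: molecules per μm³ at a concentration of 1 μM (rounded Avogadro factor)
MOLECULES_PER_UM3 = 602.0


# ---------------------------------------------------------------------------
# volume grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialGrid:
    """Regular rectangular finite-volume partition of an axis-aligned box.

    Attributes
    ----------
    lo, hi : (3,) float arrays, box bounds in μm.
    spacing : (3,) float array, mesh sizes (Δx, Δy, Δz) in μm.
    shape : (3,) int array, number of cells per axis (nx, ny, nz).
    mask : optional boolean array of length ``n_cells``; True marks cells
        that belong to the computational domain (used for non-box domains
        embedded in the grid, e.g. a pixelated sphere). ``None`` means all
        cells are active.
    """

    lo: np.ndarray
    hi: np.ndarray
    spacing: np.ndarray
    shape: np.ndarray
    mask: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_active(self) -> int:
        return self.n_cells if self.mask is None else int(self.mask.sum())

    @property
    def domain_volume(self) -> float:
        return self.n_active * self.cell_volume

    def volumes(self) -> np.ndarray:
        return np.full(self.n_cells, self.cell_volume)

    def centers(self) -> np.ndarray:
        """Cell centers, ordered lexicographically with x fastest."""
        nx, ny, nz = self.shape
        ax = [self.lo[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
              for a in range(3)]
        X, Y, Z = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
        # x fastest => Fortran-style raveling of the (ix, iy, iz) arrays
        return np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                                Z.ravel(order="F")])

    def axis_indices(self, j: np.ndarray):
        nx, ny, _ = self.shape
        ix = j % nx
        iy = (j // nx) % ny
        iz = j // (nx * ny)
        return ix, iy, iz

    def with_mask(self, mask: np.ndarray) -> "SpatialGrid":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValueError("mask length must equal n_cells")
        return SpatialGrid(self.lo, self.hi, self.spacing, self.shape, mask)


def build_box_grid(extents: Sequence[Sequence[float]],
                   spacing: Sequence[float]) -> SpatialGrid:
    """Build a regular box grid.

    Parameters
    ----------
    extents : ((x0,x1),(y0,y1),(z0,z1)) box bounds in μm.
    spacing : (Δx, Δy, Δz) in μm.  Each extent must be an integer multiple
        of its spacing to within a 1e-9 relative tolerance; anything else
        is rejected (no silent rounding).
    """
    extents = np.asarray(extents, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if extents.shape != (3, 2):
        raise ValueError("extents must be three (low, high) pairs")
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    lengths = extents[:, 1] - extents[:, 0]
    if np.any(lengths <= 0):
        raise ValueError("box must have positive extent on every axis")
    ratio = lengths / spacing
    shape = np.rint(ratio).astype(int)
    bad = np.abs(ratio - shape) > 1e-9 * np.maximum(1.0, ratio)
    if np.any(bad):
        ax = "xyz"[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"extent along {ax} ({lengths[np.flatnonzero(bad)[0]]} μm) is not "
            f"divisible by its spacing; refusing to round the mesh silently")
    return SpatialGrid(extents[:, 0].copy(), extents[:, 1].copy(),
                       spacing, shape)


def locate_cell(grid: SpatialGrid, position) -> int:
    """Return the index of the unique cell containing ``position``."""
    return int(locate_cells(grid, np.asarray(position, float)[None, :])[0])


def locate_cells(grid: SpatialGrid, positions: np.ndarray) -> np.ndarray:
    """Vectorized cell lookup with the half-open convention.

    Points exactly on an interior face belong to the higher-index cell;
    points on the global upper boundary belong to the last cell.
    """
    positions = np.asarray(positions, dtype=float)
    for a, name in enumerate("xyz"):
        if np.any(positions[:, a] < grid.lo[a]) or \
           np.any(positions[:, a] > grid.hi[a]):
            raise ValueError(f"position outside grid along {name}: bounds "
                             f"[{grid.lo[a]}, {grid.hi[a]}]")
    idx = np.floor((positions - grid.lo) / grid.spacing).astype(np.int64)
    idx = np.minimum(idx, grid.shape - 1)  # closed upper boundary
    return idx[:, 0] + grid.shape[0] * (idx[:, 1] + grid.shape[1] * idx[:, 2])


# ---------------------------------------------------------------------------
# triangulated closed surface
# ---------------------------------------------------------------------------

class SurfaceMesh:
    """Closed orientable triangulated surface.

    Stores vertices (μm) and triangles (index triples, counter-clockwise
    when viewed from outside) and derives per-element areas, outward
    normals, edge adjacency, and a barycentric-dual vertex mass used by
    the Laplace-Beltrami discretization in :mod:`hybridrd.pde`.
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.triangles = np.asarray(triangles, dtype=np.int64)
        v = self.vertices
        t = self.triangles
        e1 = v[t[:, 1]] - v[t[:, 0]]
        e2 = v[t[:, 2]] - v[t[:, 0]]
        cr = np.cross(e1, e2)
        nrm = np.linalg.norm(cr, axis=1)
        if np.any(nrm < 1e-14):
            raise ValueError("degenerate triangle (area below threshold)")
        self.areas = 0.5 * nrm
        self.normals = cr / nrm[:, None]
        self.centroids = v[t].mean(axis=1)
        self._check_closed()
        self._centroid_tree = cKDTree(self.centroids)

    # -- topology ----------------------------------------------------------
    def _check_closed(self) -> None:
        edges = np.concatenate([self.triangles[:, [0, 1]],
                                self.triangles[:, [1, 2]],
                                self.triangles[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("surface is not closed: every edge must be "
                             "shared by exactly two triangles")

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    # -- particle support --------------------------------------------------
    def point(self, tri: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Cartesian position of (triangle, barycentric-uv) coordinates."""
        t = self.triangles[tri]
        w = np.column_stack([1.0 - bary[:, 0] - bary[:, 1],
                             bary[:, 0], bary[:, 1]])
        return np.einsum("ij,ijk->ik", w, self.vertices[t])

    def locate(self, points: np.ndarray, k: int = 12):
        """Project points onto the mesh: containing triangle + barycentric.

        Searches the ``k`` nearest element centroids and picks the
        candidate whose in-plane barycentric coordinates are closest to
        the valid simplex (clamped into it if slightly outside).
        """
        points = np.asarray(points, float)
        _, cand = self._centroid_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        n = len(points)
        best_tri = np.full(n, -1, dtype=np.int64)
        best_bary = np.zeros((n, 2))
        best_pen = np.full(n, np.inf)
        v = self.vertices
        t = self.triangles
        for c in range(cand.shape[1]):
            tri = cand[:, c]
            a = v[t[tri, 0]]
            b = v[t[tri, 1]] - a
            d = v[t[tri, 2]] - a
            w = points - a
            bb = np.einsum("ij,ij->i", b, b)
            bd = np.einsum("ij,ij->i", b, d)
            dd = np.einsum("ij,ij->i", d, d)
            wb = np.einsum("ij,ij->i", w, b)
            wd = np.einsum("ij,ij->i", w, d)
            det = bb * dd - bd * bd
            u = (dd * wb - bd * wd) / det
            vv = (bb * wd - bd * wb) / det
            pen = (np.maximum(0.0, -u) + np.maximum(0.0, -vv)
                   + np.maximum(0.0, u + vv - 1.0))
            upd = pen < best_pen
            best_pen[upd] = pen[upd]
            best_tri[upd] = tri[upd]
            best_bary[upd, 0] = u[upd]
            best_bary[upd, 1] = vv[upd]
        # clamp into the simplex
        u, vv = best_bary[:, 0], best_bary[:, 1]
        u = np.clip(u, 0.0, 1.0)
        vv = np.clip(vv, 0.0, 1.0)
        s = u + vv
        over = s > 1.0
        u[over] /= s[over]
        vv[over] /= s[over]
        return best_tri, np.column_stack([u, vv])


def icosphere(radius: float = 1.0, subdivisions: int = 2,
              center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Refined-icosahedron sphere mesh (20·4**subdivisions triangles)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]],
        dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]],
        dtype=np.int64)
    for _ in range(subdivisions):
        edge_mid: dict = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                edge_mid[key] = len(vlist)
                vlist.append(m)
            return edge_mid[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c],
                          [ab, bc, ca]]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)
    verts = verts * radius + np.asarray(center, float)
    return SurfaceMesh(verts, faces)


def sphere_cell_mask(grid: SpatialGrid, radius: float,
                     center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean mask of grid cells whose centers lie inside a sphere."""
    c = grid.centers() - np.asarray(center, float)
    return (c ** 2).sum(axis=1) <= radius ** 2


# ---------------------------------------------------------------------------
# particle containers
# ---------------------------------------------------------------------------

@dataclass
class ParticleSet:
    """Discrete stochastic subsystem: positions plus one state per particle.

    ``states`` declares the admissible state labels; ``state`` stores the
    integer code of each particle's current state.  Volume particles carry
    Cartesian ``positions``; surface particles are stored exactly on the
    membrane as (triangle index, barycentric uv) pairs.
    """

    species: str
    states: tuple
    state: np.ndarray
    domain: str = "volume"                      # "volume" | "surface"
    positions: Optional[np.ndarray] = None      # (N,3), volume particles
    tri: Optional[np.ndarray] = None            # (N,), surface particles
    bary: Optional[np.ndarray] = None           # (N,2)

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=np.int64)
        if np.any(self.state < 0) or np.any(self.state >= len(self.states)):
            raise ValueError("state codes outside the declared state set")

    @property
    def n(self) -> int:
        return len(self.state)

    def state_code(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r} for species "
                           f"{self.species!r} (declared: {self.states})")

    def cartesian(self, mesh: Optional[SurfaceMesh] = None) -> np.ndarray:
        if self.domain == "volume":
            return self.positions
        if mesh is None:
            raise ValueError("surface particles need their SurfaceMesh")
        return mesh.point(self.tri, self.bary)

    def copy(self) -> "ParticleSet":
        return ParticleSet(
            self.species, self.states, self.state.copy(), self.domain,
            None if self.positions is None else self.positions.copy(),
            None if self.tri is None else self.tri.copy(),
            None if self.bary is None else self.bary.copy())


def bin_particles(particles: ParticleSet, grid: SpatialGrid,
                  state: str) -> np.ndarray:
    """Number density (per μm³) of particles in ``state``, per grid cell.

    Satisfies the exact mass identity
    ``sum_j density_j * |ω_j| == number of particles in that state``.
    """
    code = particles.state_code(state)
    counts = np.zeros(grid.n_cells)
    sel = particles.state == code
    if sel.any():
        j = locate_cells(grid, particles.positions[sel])
        np.add.at(counts, j, 1.0)
    return counts / grid.cell_volume


def bin_surface_particles(particles: ParticleSet, mesh: SurfaceMesh,
                          state: str) -> np.ndarray:
    """Surface density (per μm²) of particles in ``state``, per element."""
    code = particles.state_code(state)
    counts = np.zeros(mesh.n_elements)
    sel = particles.state == code
    if sel.any():
        np.add.at(counts, particles.tri[sel], 1.0)
    return counts / mesh.areas
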