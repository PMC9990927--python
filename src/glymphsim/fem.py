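"""Continuous piecewise-linear (P1) finite elements on tetrahedral meshes.

Minimal assembly kernels used by the pressure and transport solvers:
stiffness, (weighted) consistent mass, convection, and boundary (facet) mass
and load operators, all returned as scipy sparse matrices over the mesh
vertices.  Everything is vectorized over cells.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import Mesh

__all__ = [
    "cell_gradients", "stiffness_matrix", "mass_matrix", "lumped_mass",
    "convection_matrix", "boundary_mass_matrix", "boundary_load",
    "integrate", "cell_means", "nodal_gradient", "DirichletSystem",
]


def cell_gradients(mesh: Mesh) -> np.ndarray:
    """Gradients of the four P1 basis functions per cell, shape (m, 4, 3)."""
    if "p1_gradients" in mesh._cache:
        return mesh._cache["p1_gradients"]
    x = mesh.vertices[mesh.cells]                      # (m, 4, 3)
    d = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)       # columns are edges
    dinv = np.linalg.inv(d)                            # (m, 3, 3)
    g = np.empty((mesh.n_cells, 4, 3))
    g[:, 1:, :] = dinv
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    mesh._cache["p1_gradients"] = g
    return g


def _coo(mesh: Mesh, local: np.ndarray) -> sp.csr_matrix:
    """Assemble per-cell 4x4 local matrices into a global CSR matrix."""
    cells = mesh.cells
    rows = np.repeat(cells, 4, axis=1).ravel()
    cols = np.tile(cells, (1, 4)).ravel()
    a = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_vertices, mesh.n_vertices))
    return a.tocsr()


def stiffness_matrix(mesh: Mesh, coeff: float | np.ndarray = 1.0) -> sp.csr_matrix:
    """Assemble  int coeff grad(u) . grad(q) dx  (coeff scalar or per cell)."""
    g = cell_gradients(mesh)
    vol = mesh.cell_volumes
    c = np.broadcast_to(np.asarray(coeff, dtype=float), vol.shape)
    local = np.einsum("c,cad,cbd->cab", c * vol, g, g)
    return _coo(mesh, local)


_MASS_LOCAL = (np.ones((4, 4)) + np.eye(4)) / 20.0


def mass_matrix(mesh: Mesh, weight: float | np.ndarray = 1.0) -> sp.csr_matrix:
    """Consistent mass matrix  int weight u q dx  (weight per cell)."""
    vol = mesh.cell_volumes
    w = np.broadcast_to(np.asarray(weight, dtype=float), vol.shape)
    local = (w * vol)[:, None, None] * _MASS_LOCAL[None]
    return _coo(mesh, local)


def lumped_mass(mesh: Mesh) -> np.ndarray:
    """Vector of int phi_a dx (row sums of the mass matrix)."""
    if "p1_lumped_mass" in mesh._cache:
        return mesh._cache["p1_lumped_mass"]
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.cells.ravel(),
              np.repeat(mesh.cell_volumes / 4.0, 4))
    mesh._cache["p1_lumped_mass"] = out
    return out


def convection_matrix(mesh: Mesh, velocity_cells: np.ndarray) -> sp.csr_matrix:
    """Assemble  -int u (w . grad q) dx  for a cellwise-constant velocity w.

    This is the volume part of the weak conservative convection term
    div(u w); the boundary contribution is handled by the caller through the
    boundary-condition treatment (dropped for weak zero-total-flux walls,
    eliminated rows for Dirichlet walls).
    """
    g = cell_gradients(mesh)
    vol = mesh.cell_volumes
    wdotg = np.einsum("cd,cad->ca", velocity_cells, g)    # (m, 4)
    # entry (a, b): -V/4 * (w . grad phi_a), independent of b
    local = np.repeat((-vol[:, None] / 4.0 * wdotg)[:, :, None], 4, axis=2)
    return _coo(mesh, local)


def boundary_mass_matrix(mesh: Mesh) -> sp.csr_matrix:
    """Facet mass matrix  int_boundary u q ds  over all boundary faces."""
    faces = mesh.boundary_faces
    areas = mesh.boundary_areas
    local = areas[:, None, None] * ((np.ones((3, 3)) + np.eye(3)) / 12.0)[None]
    rows = np.repeat(faces, 3, axis=1).ravel()
    cols = np.tile(faces, (1, 3)).ravel()
    a = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_vertices, mesh.n_vertices))
    return a.tocsr()


def boundary_load(mesh: Mesh) -> np.ndarray:
    """Vector of int_boundary phi_a ds over all boundary faces."""
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.boundary_faces.ravel(),
              np.repeat(mesh.boundary_areas / 3.0, 3))
    return out


def integrate(mesh: Mesh, nodal: np.ndarray) -> float:
    """Exact integral of a P1 field over the mesh."""
    return float(lumped_mass(mesh) @ nodal)


def cell_means(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Cellwise mean of a nodal field."""
    return nodal[mesh.cells].mean(axis=1)


def nodal_gradient(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Cellwise-constant gradient of a P1 field, shape (m, 3)."""
    g = cell_gradients(mesh)
    return np.einsum("ca,cad->cd", nodal[mesh.cells], g)


class DirichletSystem:
    """Linear system with Dirichlet degrees of freedom eliminated.

    Stores a sparse LU factorization of the free-free block so that repeated
    solves with updated right-hand sides and Dirichlet values (as in implicit
    time stepping with a time-dependent boundary value) reuse the
    factorization.
    """

    def __init__(self, matrix: sp.spmatrix, fixed: np.ndarray):
        from scipy.sparse.linalg import splu
        n = matrix.shape[0]
        self.n = n
        self.fixed = np.asarray(fixed, dtype=np.int64)
        mask = np.zeros(n, dtype=bool)
        mask[self.fixed] = True
        self.free = np.nonzero(~mask)[0]
        a = matrix.tocsc()
        self.a_ff = a[self.free][:, self.free]
        self.a_fd = a[self.free][:, self.fixed]
        # Symmetric diagonal equilibration keeps threshold pivoting close to
        # the diagonal (the raw blocks differ by many orders of magnitude,
        # which otherwise ruins the fill-reducing ordering), and MMD on
        # A^T+A gives far sparser LU factors than COLAMD for these
        # symmetric-pattern 3-D stencils.
        d = np.abs(self.a_ff.diagonal())
        d[d == 0.0] = 1.0
        self._scale = 1.0 / np.sqrt(d)
        ds = sp.diags(self._scale)
        self.lu = splu((ds @ self.a_ff @ ds).tocsc(),
                       permc_spec="MMD_AT_PLUS_A")
        self._matrix = a

    def solve(self, rhs: np.ndarray, dirichlet_values: np.ndarray | float = 0.0
              ) -> np.ndarray:
        """Solve A x = rhs with x[fixed] = dirichlet_values."""
        vals = np.broadcast_to(np.asarray(dirichlet_values, dtype=float),
                               self.fixed.shape)
        b = rhs[self.free] - self.a_fd @ vals
        x = np.empty(self.n)
        x[self.free] = self._scale * self.lu.solve(self._scale * b)
        x[self.fixed] = vals
        return x

    def residual(self, x: np.ndarray, rhs: np.ndarray) -> float:
        """Relative residual of the free equations."""
        r = self._matrix[self.free] @ x - rhs[self.free]
        scale = max(float(np.linalg.norm(rhs[self.free])), 1e-300)
        return float(np.linalg.norm(r)) / scale
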