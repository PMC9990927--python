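"""Steady coupled Darcy pressure problem of the multi-compartment model.

For every compartment j the static (rigid-matrix) MPET balance

    -div( (kappa_j / mu_j) grad p_j )
        = sum_i gamma_ji [ (p_i - p_j) - sigma_ij (pi_i - pi_j) ]

is discretized with continuous P1 elements and solved monolithically for all
compartments at once.  The divergence acts on the Darcy (superficial) flux
v_j = -(kappa_j/mu_j) grad p_j, and the right-hand side is the volumetric
exchange per unit tissue volume — the convention under which the gamma
coefficients were derived (total flow over pressure drop and brain volume),
so the lumped flow circuit (arterial inflow, branching drops, CSF
production) is reproduced exactly.  The porosity-normalized pointwise
source r_j of :func:`glymphsim.model.fluid_source` remains available for
audit.
Boundary conditions per compartment: Robin (outflux = L (p - p_ext)),
Neumann (prescribed total influx, distributed uniformly over the surface) or
Dirichlet (fixed boundary pressure).  Robin/Neumann data act on the natural
flux of the assembled operator, i.e. they prescribe actual volumetric rates.

From the solved pressures the module derives pore velocities
u_j = -kappa_j/(phi_j mu_j) grad p_j, their summary statistics, the
inter-compartment exchange rates Q_{j,i} = int gamma_ji (p_i - p_j) dx and
the boundary (SAS) exchange rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fem
from .geometry import Mesh
from .model import ModelError, ModelSpec

__all__ = ["PressureSolution", "solve_pressure", "pore_velocity",
           "velocity_stats", "exchange_flux", "boundary_flux"]


def _beta(spec: ModelSpec, j: str) -> float:
    """Darcy mobility of the assembled operator, kappa / mu.

    The assembled flux -(kappa/mu) grad p is the Darcy (superficial) flux of
    the compartment; dividing it by the porosity gives the pore velocity the
    velocity reports use.
    """
    t = spec.table
    return t.kappa[j] / t.mu[j]


@dataclass
class PressureSolution:
    """Steady pressures, pore velocities and solver diagnostics."""

    spec: ModelSpec
    mesh: Mesh
    p: dict[str, np.ndarray]              # nodal pressures, Pa
    u: dict[str, np.ndarray] = field(default_factory=dict)  # cell velocities
    residual: float = 0.0
    method: str = "direct"

    def velocity(self, j: str) -> np.ndarray:
        """Pore velocity field of compartment j, cellwise (mm/s)."""
        if j not in self.u:
            self.u[j] = pore_velocity(self.mesh, self.p[j], self.spec, j)
        return self.u[j]


def _assemble(spec: ModelSpec, mesh: Mesh):
    comps = list(spec.compartments)
    index = {j: k for k, j in enumerate(comps)}
    n = mesh.n_vertices
    K = fem.stiffness_matrix(mesh)
    M = fem.mass_matrix(mesh)
    Mb = fem.boundary_mass_matrix(mesh)
    bl = fem.boundary_load(mesh)
    lump = fem.lumped_mass(mesh)

    blocks = [[None] * len(comps) for _ in comps]
    rhs = np.zeros(len(comps) * n)
    fixed_dofs: list[np.ndarray] = []
    fixed_vals: list[np.ndarray] = []
    bverts = mesh.boundary_vertices

    for j in comps:
        k = index[j]
        a_jj = _beta(spec, j) * K
        for edge in spec.edges_of(j):
            i = edge.other(j)
            # volumetric exchange per unit tissue volume: gamma (p_i - p_j),
            # the convention the gamma values were derived under (total flow
            # over pressure drop and brain volume) -- no porosity prefactor
            g = edge.gamma
            a_jj = a_jj + g * M
            a_ji = -g * M
            ki = index[i]
            blocks[k][ki] = a_ji if blocks[k][ki] is None else blocks[k][ki] + a_ji
            dpi = spec.table.pi[i] - spec.table.pi[j]
            rhs[k * n:(k + 1) * n] += (-g * edge.sigma_osmotic * dpi) * lump

        bc = spec.pressure_bcs[j]
        if bc.kind == "robin":
            a_jj = a_jj + bc.conductance * Mb
            rhs[k * n:(k + 1) * n] += bc.conductance * bc.value * bl
        elif bc.kind == "neumann":
            rhs[k * n:(k + 1) * n] += (bc.total_influx / mesh.surface_area) * bl
        elif bc.kind == "dirichlet":
            fixed_dofs.append(k * n + bverts)
            fixed_vals.append(np.full(bverts.size, bc.value))
        else:
            raise ModelError(f"unknown pressure BC kind {bc.kind!r}")
        blocks[k][k] = a_jj

    matrix = sp.bmat(blocks, format="csr")
    if fixed_dofs:
        fixed = np.concatenate(fixed_dofs)
        vals = np.concatenate(fixed_vals)
    else:
        fixed = np.empty(0, dtype=np.int64)
        vals = np.empty(0)
    return matrix, rhs, fixed, vals, index


def solve_pressure(spec: ModelSpec, mesh: Mesh, method: str = "auto",
                   rtol: float | None = None) -> PressureSolution:
    """Solve the coupled steady Darcy system of all compartments.

    ``method`` is "direct" (sparse LU), "iterative" (Jacobi-preconditioned
    CG on the phi-symmetrized system) or "auto" (direct for small systems,
    iterative for large ones, where the LU fill of the block-coupled 3-D
    stencil becomes expensive).  The relative residual of the assembled
    system is checked against ``rtol`` (defaults: 1e-10 direct, 1e-8
    iterative) and reported in the solution.
    """
    if not spec.pressure_active:
        raise ModelError("test case 1 has no pressure problem to solve")
    spec.validate()
    if method == "auto":
        method = ("direct"
                  if mesh.n_vertices * len(spec.compartments) <= 12000
                  else "iterative")
    rtol = rtol if rtol is not None else (1e-10 if method == "direct" else 1e-8)

    matrix, rhs, fixed, vals, index = _assemble(spec, mesh)
    n = mesh.n_vertices

    if method == "direct":
        system = fem.DirichletSystem(matrix, fixed)
        x = system.solve(rhs, vals)
    elif method == "iterative":
        # The assembled system is symmetric positive definite (stiffness +
        # equal-gamma coupling blocks + Robin boundary terms), so Jacobi-
        # preconditioned CG converges quickly even on large meshes.
        from scipy.sparse.linalg import cg
        mask = np.zeros(matrix.shape[0], dtype=bool)
        mask[fixed] = True
        free = np.nonzero(~mask)[0]
        a = matrix.tocsc()
        a_ff = a[free][:, free].tocsc()
        b = rhs[free] - a[free][:, fixed] @ vals
        pre = sp.diags(1.0 / a_ff.diagonal())
        xf, info = cg(a_ff, b, M=pre, rtol=min(rtol * 1e-2, 1e-12),
                      maxiter=50000)
        if info != 0:
            raise ModelError(f"CG did not converge (info={info})")
        x = np.empty(matrix.shape[0])
        x[free] = xf
        x[fixed] = vals
    else:
        raise ModelError(f"unknown solve method {method!r}")

    # residual of the non-Dirichlet equations
    mask = np.zeros(matrix.shape[0], dtype=bool)
    mask[fixed] = True
    free = ~mask
    res_vec = matrix @ x - rhs
    scale = max(float(np.linalg.norm(rhs[free])),
                float(np.abs(matrix.data).max()) * float(np.linalg.norm(x)),
                1e-300)
    residual = float(np.linalg.norm(res_vec[free])) / scale
    if residual > max(rtol * 100, 1e-8):
        raise ModelError(f"pressure solve residual {residual:.2e} exceeds "
                         f"tolerance")

    p = {j: x[k * n:(k + 1) * n] for j, k in index.items()}
    return PressureSolution(spec=spec, mesh=mesh, p=p, residual=residual,
                            method=method)


def pore_velocity(mesh: Mesh, p_nodal: np.ndarray, spec: ModelSpec, j: str
                  ) -> np.ndarray:
    """Pore velocity u_j = -kappa_j/(phi_j mu_j) grad p_j, cellwise (mm/s)."""
    t = spec.table
    coeff = t.kappa[j] / (t.phi[j] * t.mu[j])
    return -coeff * fem.nodal_gradient(mesh, p_nodal)


def velocity_stats(u_cells: np.ndarray, mesh: Mesh) -> tuple[float, float]:
    """(average, maximum) of the velocity magnitude over the domain (mm/s).

    The average is the volume mean of |u|; the maximum is the essential
    supremum over cells.
    """
    speed = np.linalg.norm(u_cells, axis=1)
    u_aver = float((speed * mesh.cell_volumes).sum() / mesh.volume)
    u_max = float(speed.max()) if speed.size else 0.0
    return u_aver, u_max


def exchange_flux(solution: PressureSolution, i: str, j: str,
                  include_osmotic: bool = False) -> float:
    """Fluid volume rate Q_{j,i} = int gamma_ji (p_i - p_j) dx (mm^3/s).

    Positive means net transfer from i into j.  With ``include_osmotic`` the
    osmotic driving term -sigma_ij (pi_i - pi_j) is added to the integrand
    (needed for exact volume bookkeeping across semi-permeable membranes).
    """
    spec, mesh = solution.spec, solution.mesh
    edge = spec.edge(i, j)
    lump = fem.lumped_mass(mesh)
    drive = solution.p[i] - solution.p[j]
    q = edge.gamma * float(lump @ drive)
    if include_osmotic:
        dpi = spec.table.pi[i] - spec.table.pi[j]
        q -= edge.gamma * edge.sigma_osmotic * dpi * mesh.volume
    return q


def boundary_flux(solution: PressureSolution, j: str,
                  convention: str = "darcy") -> float:
    """Net boundary outflux Q_{j,SAS} of compartment j (mm^3/s, > 0 = out).

    ``convention`` selects the bookkeeping of the reported number: "darcy"
    is the surface integral of -(kappa/mu) dp/dnu, the natural flux of the
    assembled operator (closes the discrete volume balance against the
    exchange terms exactly); "phi_weighted" multiplies by phi_j, the
    alternative bookkeeping in which the operator mobility carries the
    porosity.
    """
    if convention not in ("darcy", "phi_weighted"):
        raise ModelError(f"unknown flux convention {convention!r}")
    spec, mesh = solution.spec, solution.mesh
    bc = spec.pressure_bcs[j]
    if bc.kind == "robin":
        bmass = fem.boundary_mass_matrix(mesh)
        ones = np.ones(mesh.n_vertices)
        q_out = bc.conductance * float(
            ones @ (bmass @ solution.p[j]) - bc.value * mesh.surface_area)
    elif bc.kind == "neumann":
        q_out = -bc.total_influx
    else:  # dirichlet: recover from the residual of the boundary rows
        q_out = _dirichlet_outflux(solution, j)
    if convention == "phi_weighted":
        q_out *= spec.table.phi[j]
    return q_out


def _dirichlet_outflux(solution: PressureSolution, j: str) -> float:
    """Discrete boundary outflux of a Dirichlet compartment.

    Summing the (unconstrained) weak-form residual over the Dirichlet rows
    recovers int_boundary beta dp/dnu ds, since the residual vanishes on
    every interior row and the P1 basis is a partition of unity.
    """
    spec, mesh = solution.spec, solution.mesh
    K = fem.stiffness_matrix(mesh)
    M = fem.mass_matrix(mesh)
    lump = fem.lumped_mass(mesh)
    p_j = solution.p[j]
    res = _beta(spec, j) * (K @ p_j)
    for edge in spec.edges_of(j):
        i = edge.other(j)
        g = edge.gamma
        dpi = spec.table.pi[i] - spec.table.pi[j]
        res -= g * (M @ (solution.p[i] - p_j)) - g * edge.sigma_osmotic * dpi * lump
    flux_in_weak = res[mesh.boundary_vertices].sum()
    # res_a = int beta dp/dnu phi_a on boundary rows; outflux = -int beta dp/dnu
    return -float(flux_in_weak)
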