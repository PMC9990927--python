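"""Independent reference solutions for verification.

Nothing in this module touches the finite-element assembly: the diffusion
oracle is an eigenfunction series (cross-checked by a brute-force radial
finite-difference integrator), and the pressure oracle is a second-order
radial finite-difference/finite-volume solver for spherically symmetric
coupled Darcy systems.  These are the trusted comparators the 3-D solvers
are tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import quad
from scipy.sparse.linalg import spsolve

__all__ = ["RadialProfile", "ball_diffusion_mass", "ball_diffusion_mass_fd",
           "radial_pressure_bvp", "RadialCompartment", "RadialEdge"]


# ---------------------------------------------------------------------------
# Diffusion in a ball, homogeneous Dirichlet: eigenfunction series
# ---------------------------------------------------------------------------

def ball_diffusion_mass(radius: float, diffusion: float, sigma: float,
                        times, tol: float = 1e-10, n_max: int = 2000
                        ) -> np.ndarray:
    """Remaining mass fraction for heat-equation decay in a ball.

    A centred Gaussian initial condition exp(-r^2/sigma^2) diffuses in a
    ball of the given radius with c = 0 on the surface.  Expanding in the
    radial Dirichlet eigenfunctions sin(n pi r / R)/r, the remaining mass
    fraction at time t is

        m(t)/m(0) = sum_n b_n I_n exp(-D (n pi / R)^2 t) / m(0),

    with coefficients computed by adaptive quadrature and the series
    truncated once the term magnitude falls below ``tol`` (the Gaussian
    spectrum decays super-exponentially, so few terms are needed).
    """
    if sigma >= radius / 3.0:
        warnings.warn("initial spread sigma is not small compared to the "
                      "ball radius; series mass fraction loses accuracy",
                      stacklevel=2)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    R, D = float(radius), float(diffusion)

    mass0 = 4.0 * np.pi * quad(
        lambda r: np.exp(-r**2 / sigma**2) * r**2, 0.0, R, limit=200)[0]

    out = np.zeros_like(times)
    for n in range(1, n_max + 1):
        k = n * np.pi / R
        num = quad(lambda r: np.exp(-r**2 / sigma**2) * np.sin(k * r) * r,
                   0.0, R, limit=200)[0]
        b_n = num / (R / 2.0)
        # int_0^R sin(k r) r dr = R^2 (-1)^(n+1) / (n pi)
        i_n = R**2 * (-1.0) ** (n + 1) / (n * np.pi)
        amplitude = 4.0 * np.pi * b_n * i_n / mass0
        out += amplitude * np.exp(-D * k**2 * times)
        if abs(amplitude) < tol and n > 4:
            break
    return out if out.shape != (1,) else out


def ball_diffusion_mass_fd(radius: float, diffusion: float, sigma: float,
                           times, n_nodes: int = 2000) -> np.ndarray:
    """Brute-force radial finite-difference comparator for the series.

    Solves dc/dt = D (1/r^2) d/dr(r^2 dc/dr) on a fine radial grid with a
    conservative finite-volume discretization.  The discrete operator is
    similar to a symmetric tridiagonal matrix (weighted by the control
    volumes), so an eigendecomposition gives the solution exactly in time;
    the only error is the O(h^2) spatial one.
    """
    from scipy.linalg import eigh_tridiagonal

    times = np.atleast_1d(np.asarray(times, dtype=float))
    R, D = float(radius), float(diffusion)
    n = n_nodes
    h = R / n
    r = np.linspace(0.0, R, n + 1)
    c0 = np.exp(-r**2 / sigma**2)
    c0[-1] = 0.0

    # control volumes V_k = (r_{k+1/2}^3 - r_{k-1/2}^3)/3 (per 4 pi)
    r_half = np.concatenate([[0.0], (r[:-1] + r[1:]) / 2.0, [R]])
    vol = (r_half[1:] ** 3 - r_half[:-1] ** 3) / 3.0

    # interior unknowns k = 0..n-1 (c_n = 0 Dirichlet);
    # A = D V^-1 T with T symmetric tridiagonal:
    #   T[k,k] = -(a_plus + a_minus), T[k,k-1] = a_minus = r_{k-1/2}^2/h
    a_face = r_half[:n + 1] ** 2 / h          # a_minus(k) = a_face[k]
    main = -(a_face[1:n + 1] + a_face[:n]) / vol[:n]
    off = a_face[1:n] / np.sqrt(vol[1:n] * vol[:n - 1])
    # symmetrized B = V^(1/2) A V^(-1/2); same diagonal as A
    evals, evecs = eigh_tridiagonal(D * main, D * off)

    w = np.sqrt(vol[:n])
    z = evecs.T @ (w * c0[:-1])               # spectral coefficients
    proj = evecs.T @ w                        # mass functional in eigenbasis
    mass0 = float((vol[:n] * c0[:-1]).sum())
    out = np.empty_like(times)
    for idx, t in enumerate(times):
        out[idx] = float(proj @ (np.exp(evals * t) * z)) / mass0
    return out


# ---------------------------------------------------------------------------
# Coupled radial Darcy boundary-value problem
# ---------------------------------------------------------------------------

@dataclass
class RadialCompartment:
    """One compartment of the radial oracle (primitive inputs only)."""

    name: str
    beta: float          # Darcy coefficient of the operator, mm^2/(Pa s)
    phi: float = 1.0
    bc: tuple = ("neumann", 0.0)
    # ("dirichlet", value) | ("robin", conductance, p_ext)
    # | ("neumann", total_influx)


@dataclass
class RadialEdge:
    """Coupling gamma and constant osmotic drive between two compartments."""

    i: str
    j: str
    gamma: float
    drive: float = 0.0    # sigma_ij (pi_i - pi_j), Pa, seen from j


@dataclass
class RadialProfile:
    """Radial solution profiles and boundary fluxes."""

    radii: np.ndarray
    profiles: dict[str, np.ndarray]
    boundary_outflux: dict[str, float]    # mm^3/s, operator-level, > 0 = out

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radial grid must be strictly increasing")

    def interp(self, name: str, r) -> np.ndarray:
        return np.interp(np.abs(r), self.radii, self.profiles[name])


def _radial_system(comps: list[RadialCompartment], edges: list[RadialEdge],
                   radius: float, n: int):
    h = radius / n
    r = np.linspace(0.0, radius, n + 1)
    r_half = np.concatenate([[0.0], (r[:-1] + r[1:]) / 2.0, [radius]])
    vol = (r_half[1:] ** 3 - r_half[:-1] ** 3) / 3.0   # per 4 pi steradian
    nn = n + 1
    index = {c.name: k for k, c in enumerate(comps)}

    rows, cols, vals = [], [], []
    rhs = np.zeros(len(comps) * nn)
    dirichlet: list[tuple[int, float]] = []

    def add(row, col, val):
        rows.append(row)
        cols.append(col)
        vals.append(val)

    for c in comps:
        k0 = index[c.name] * nn
        # conservative FV Laplacian: -beta [r^2 p']_{k-1/2}^{k+1/2} = vol_k src
        for k in range(nn):
            row = k0 + k
            a_plus = c.beta * r_half[k + 1] ** 2 / h if k < n else 0.0
            a_minus = c.beta * r_half[k] ** 2 / h if k > 0 else 0.0
            if k < n:
                add(row, k0 + k, a_plus)
                add(row, k0 + k + 1, -a_plus)
            if k > 0:
                add(row, k0 + k, a_minus)
                add(row, k0 + k - 1, -a_minus)
        kind = c.bc[0]
        row = k0 + n
        if kind == "dirichlet":
            dirichlet.append((row, float(c.bc[1])))
        elif kind == "robin":
            cond, p_ext = float(c.bc[1]), float(c.bc[2])
            # outflux density L (p - p_ext) on the surface r = R
            add(row, k0 + n, cond * radius**2)
            rhs[row] += cond * p_ext * radius**2
        elif kind == "neumann":
            total_influx = float(c.bc[1])
            rhs[row] += total_influx / (4.0 * np.pi)
        else:
            raise ValueError(f"unknown radial BC kind {kind!r}")

    for e in edges:
        ki, kj = index[e.i] * nn, index[e.j] * nn
        for k in range(nn):
            w = e.gamma * vol[k]
            # row j: -gamma (p_i - p_j - drive) moved left
            add(kj + k, kj + k, w)
            add(kj + k, ki + k, -w)
            rhs[kj + k] += -w * e.drive
            # row i: drive flips sign
            add(ki + k, ki + k, w)
            add(ki + k, kj + k, -w)
            rhs[ki + k] += w * e.drive

    a = sp.coo_matrix((vals, (rows, cols)),
                      shape=(len(comps) * nn, len(comps) * nn)).tolil()
    for row, value in dirichlet:
        a.rows[row] = [row]
        a.data[row] = [1.0]
        rhs[row] = value
    return a.tocsc(), rhs, r, index


def _solve_once(comps, edges, radius, n):
    a, rhs, r, index = _radial_system(comps, edges, radius, n)
    x = spsolve(a, rhs)
    nn = n + 1
    return r, {name: x[k * nn:(k + 1) * nn] for name, k in index.items()}


def radial_pressure_bvp(comps: list[RadialCompartment],
                        edges: list[RadialEdge],
                        radius: float, resolution: int = 2000,
                        richardson: bool = True) -> RadialProfile:
    """Spherically symmetric coupled Darcy system, second-order FD/FV.

    Solves -beta_j (1/r^2)(r^2 p_j')' = sum gamma [(p_i - p_j) - drive]
    on (0, R) with symmetry at the origin.  With ``richardson`` the
    resolution is doubled once and the profiles extrapolated to fourth-order
    accuracy on the coarse grid.
    """
    names = [c.name for c in comps]
    if len(set(names)) != len(names):
        raise ValueError("compartment names must be unique")
    r, prof = _solve_once(comps, edges, radius, resolution)
    if richardson:
        _, prof2 = _solve_once(comps, edges, radius, 2 * resolution)
        prof = {name: (4.0 * prof2[name][::2] - prof[name]) / 3.0
                for name in prof}

    outflux = {}
    for c in comps:
        p = prof[c.name]
        kind = c.bc[0]
        if kind == "robin":
            outflux[c.name] = 4.0 * np.pi * radius**2 * c.bc[1] * (
                p[-1] - c.bc[2])
        elif kind == "neumann":
            outflux[c.name] = -float(c.bc[1])
        else:
            # one-sided second-order derivative at R; outflux = -beta p'(R)
            h = radius / resolution
            dpdr = (3 * p[-1] - 4 * p[-2] + p[-3]) / (2 * h)
            outflux[c.name] = 4.0 * np.pi * radius**2 * c.beta * (-dpdr)
    return RadialProfile(radii=r, profiles=prof, boundary_outflux=outflux)
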