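"""Quantities of interest: relative masses, rate constants, transfer rates.

Summary quantities reported from a run, in the units the physiology
literature uses: relative masses are dimensionless (normalized by the t = 0
ECS mass), velocities are reported in um/s, volumetric fluxes in uL/min, and
the clearance rate constant in 1/min.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fem
from .geometry import Mesh, Region
from .model import ModelError, ModelSpec
from .pressure import PressureSolution, velocity_stats
from .transport import TransportResult
from .units import mm3_per_s_to_ul_per_min, mm_per_s_to_um_per_s

__all__ = ["relative_mass", "rate_constant", "solute_transfer_mass",
           "peclet", "qoi_table"]


def relative_mass(spec: ModelSpec, mesh: Mesh,
                  c: dict[str, np.ndarray], c_e0: np.ndarray,
                  region: Region | None = None) -> float:
    """Relative tracer mass sum_j int phi_j c_j / int phi_e c_e(0).

    Over the whole domain by default, or restricted to a sampling ``region``
    (both numerator and denominator are then integrated over the region).
    """
    lump = fem.lumped_mass(mesh)
    phi = spec.table.phi
    if region is None:
        num = sum(phi[j] * float(lump @ c[j]) for j in spec.compartments)
        den = phi["e"] * float(lump @ c_e0)
    else:
        vols = mesh.cell_volumes[region.cell_indicator]
        num = sum(phi[j] * float(
            (fem.cell_means(mesh, c[j])[region.cell_indicator] * vols).sum())
            for j in spec.compartments)
        den = phi["e"] * float(
            (fem.cell_means(mesh, c_e0)[region.cell_indicator] * vols).sum())
    if den <= 0:
        raise ModelError("initial tracer mass in the region is zero; "
                         "relative mass is undefined")
    return num / den


def rate_constant(times_min: np.ndarray, c_tot: np.ndarray,
                  t_first: float = 0.0) -> float:
    """Exponential-decay rate constant k (1/min) between two time points.

    Assumes c_tot(t) ~ exp(-k t) between ``t_first`` and the final time:
    k = -ln(c(T)/c(t_first)) / (T - t_first).
    """
    times_min = np.asarray(times_min, dtype=float)
    c_tot = np.asarray(c_tot, dtype=float)
    i0 = int(np.argmin(np.abs(times_min - t_first)))
    c0, cT = c_tot[i0], c_tot[-1]
    if c0 <= 0 or cT <= 0:
        raise ModelError("rate constant requires positive masses")
    span = times_min[-1] - times_min[i0]
    if span <= 0:
        raise ModelError("rate constant requires an increasing time grid")
    return -float(np.log(cT / c0)) / float(span)


def solute_transfer_mass(c: dict[str, np.ndarray],
                         pressure: PressureSolution | None,
                         spec: ModelSpec, mesh: Mesh,
                         i: str, j: str) -> float:
    """Tracer mass rate M_ji from compartment i into j (mass/s),

        M_ji = int [ lambda_ji (c_i - c_j)
                     + (c_j + c_i)/2 gamma~_ji (p_i - p_j - sigma dpi) ] dx.
    """
    edge = spec.edge(i, j)
    lump = fem.lumped_mass(mesh)
    total = edge.lam * float(lump @ (c[i] - c[j]))
    if edge.gamma_tilde != 0.0:
        if pressure is not None:
            dp = fem.cell_means(mesh, pressure.p[i] - pressure.p[j])
        else:
            dp = np.zeros(mesh.n_cells)
        dpi = spec.table.pi[i] - spec.table.pi[j]
        drive = dp - edge.sigma_osmotic * dpi
        cbar = 0.5 * (fem.cell_means(mesh, c[i]) + fem.cell_means(mesh, c[j]))
        total += edge.gamma_tilde * float(
            (cbar * drive * mesh.cell_volumes).sum())
    return total


def peclet(u: float, l_char: float, diffusion: float) -> float:
    """Peclet number Pe = u L / D (convective over diffusive transport)."""
    if diffusion <= 0:
        raise ModelError(f"diffusion must be > 0, got {diffusion}")
    if l_char <= 0:
        raise ModelError(f"characteristic length must be > 0, got {l_char}")
    return u * l_char / diffusion


def qoi_table(result: TransportResult,
              pressure: PressureSolution | None = None,
              l_char: float = 1.0) -> pd.DataFrame:
    """Long-format per-step QoI report of one run.

    Columns: t_min, c_tot, g, per-compartment masses, per-cube c_omega.
    If a pressure solution is given, a summary row block of velocities
    (um/s, converted from the pore velocities) and Peclet numbers is
    attached as DataFrame ``attrs["velocity_stats"]``.
    """
    data: dict[str, np.ndarray] = {
        "t_min": result.times_min,
        "c_tot": result.c_tot,
        "g": result.g,
    }
    for j, series in result.mass.items():
        data[f"mass_{j}"] = series
    for side, series in result.region_mass.items():
        data[f"c_cube_{side:g}mm"] = series
    frame = pd.DataFrame(data)

    if pressure is not None:
        rows = []
        for j in pressure.spec.compartments:
            u_aver, u_max = velocity_stats(pressure.velocity(j),
                                           pressure.mesh)
            rows.append({
                "compartment": j,
                "u_aver_um_per_s": mm_per_s_to_um_per_s(u_aver),
                "u_max_um_per_s": mm_per_s_to_um_per_s(u_max),
                "peclet": peclet(u_aver, l_char,
                                 pressure.spec.table.diffusion[j]),
            })
        frame.attrs["velocity_stats"] = pd.DataFrame(rows)
        from .pressure import boundary_flux, exchange_flux
        flows = []
        for e in pressure.spec.edges:
            flows.append({
                "pair": f"{e.j}<-{e.i}",
                "Q_ul_per_min": mm3_per_s_to_ul_per_min(
                    exchange_flux(pressure, e.i, e.j)),
            })
        for j in pressure.spec.compartments:
            flows.append({
                "pair": f"{j}->SAS",
                "Q_ul_per_min": mm3_per_s_to_ul_per_min(
                    boundary_flux(pressure, j)),
            })
        frame.attrs["flows"] = pd.DataFrame(flows)
    return frame
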