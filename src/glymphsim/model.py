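"""Compartment graphs, exchange source terms and boundary-condition models.

A :class:`ModelSpec` bundles the compartment set of one test case, the
resolved exchange edges, and the pressure/concentration boundary conditions:

* test case 1 — pure diffusion in the ECS (no pressure problem);
* test case 2 — four CSF/ISF compartments (pa, pc, pv, e) exchanging fluid
  and solute, CSF entering along periarterial spaces;
* test case 3 — the seven-compartment system adding arterial, capillary and
  venous blood with vessel-wall leakage and branching blood flow.

The fluid exchange source of compartment j is

    r_j = (1/phi_j) sum_i gamma_ji [ (p_i - p_j) - sigma_ij (pi_i - pi_j) ]

and the solute exchange source is

    s_j = (1/phi_j) sum_i [ lambda_ji (c_i - c_j)
          + (c_j + c_i)/2 * gamma~_ji (p_i - p_j - sigma_ij (pi_i - pi_j)) ]

with the arithmetic-mean concentration convention for the advective (solvent
drag) term.  Edges between directly connected vessels ("branching") carry no
membrane: P = 0 and sigma_reflect = 1, so they transfer fluid but no solute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterTable, baseline_table, pair_key

__all__ = [
    "Edge", "PressureBC", "ModelSpec", "ModelError", "build_test_case",
    "fluid_source", "solute_source", "CASE_EDGES",
]


class ModelError(ValueError):
    """Inconsistent model specification."""


@dataclass(frozen=True)
class Edge:
    """One resolved exchange connection between compartments i and j."""

    i: str
    j: str
    kind: str              # "membrane" | "branching"
    gamma: float           # 1/(s Pa)
    gamma_tilde: float     # 1/(s Pa)
    lam: float             # 1/s
    sigma_osmotic: float   # reflection in the fluid equation

    def other(self, tag: str) -> str:
        if tag == self.i:
            return self.j
        if tag == self.j:
            return self.i
        raise ModelError(f"edge ({self.i}, {self.j}) does not touch {tag!r}")


@dataclass(frozen=True)
class PressureBC:
    """Boundary condition of one compartment's pressure equation on dOmega.

    kinds:
      ``robin``     outflux = conductance * (p - external_pressure)
      ``neumann``   prescribed total boundary influx (mm^3/s, uniformly
                    distributed as influx/|dOmega| per unit area)
      ``dirichlet`` fixed boundary pressure (Pa)
    """

    kind: str
    value: float = 0.0            # external/dirichlet pressure, Pa
    conductance: float = 0.0      # Robin conductance
    total_influx: float = 0.0     # Neumann total inflow, mm^3/s

    @staticmethod
    def robin(conductance: float, external_pressure: float) -> "PressureBC":
        return PressureBC("robin", value=external_pressure,
                          conductance=conductance)

    @staticmethod
    def neumann(total_influx: float = 0.0) -> "PressureBC":
        return PressureBC("neumann", total_influx=total_influx)

    @staticmethod
    def dirichlet(value: float) -> "PressureBC":
        return PressureBC("dirichlet", value=value)


# Compartment-graph topologies: membrane and branching connections per case.
CASE_EDGES: dict[int, list[tuple[str, str]]] = {
    1: [],
    2: [("pa", "pc"), ("pc", "pv"), ("pa", "e"), ("pc", "e"), ("pv", "e")],
    3: [("pa", "pc"), ("pc", "pv"), ("pa", "e"), ("pc", "e"), ("pv", "e"),
        ("a", "c"), ("c", "v"), ("a", "pa"), ("c", "pc"), ("v", "pv")],
}

_SAS_MODELS = ("homogeneous", "conservation", "decay")


@dataclass
class ModelSpec:
    """A fully resolved model configuration for one test case."""

    test_case: int
    compartments: tuple[str, ...]
    edges: list[Edge]
    table: ParameterTable
    pressure_bcs: dict[str, PressureBC]
    concentration_mode: dict[str, str]   # "sas_coupled" | "zero_total_flux"
    sas_model: str = "decay"

    @property
    def pressure_active(self) -> bool:
        return len(self.pressure_bcs) > 0

    @property
    def sas_coupled(self) -> tuple[str, ...]:
        return tuple(j for j in self.compartments
                     if self.concentration_mode[j] == "sas_coupled")

    def edges_of(self, tag: str) -> list[Edge]:
        return [e for e in self.edges if tag in (e.i, e.j)]

    def edge(self, i: str, j: str) -> Edge:
        key = pair_key(i, j)
        for e in self.edges:
            if pair_key(e.i, e.j) == key:
                return e
        raise ModelError(f"pair ({i}, {j}) is not an edge of test case "
                         f"{self.test_case}")

    def validate(self) -> "ModelSpec":
        if self.sas_model not in _SAS_MODELS:
            raise ModelError(f"unknown SAS model {self.sas_model!r}; "
                             f"expected one of {_SAS_MODELS}")
        for j in self.compartments:
            if j not in self.concentration_mode:
                raise ModelError(f"compartment {j!r} has no concentration BC")
        if self.pressure_active:
            for j in self.compartments:
                if j not in self.pressure_bcs:
                    raise ModelError(f"compartment {j!r} has no pressure BC")
            self._check_well_posed()
        for e in self.edges:
            if e.kind == "branching" and (e.lam != 0.0 or e.gamma_tilde != 0.0):
                raise ModelError(
                    f"branching edge ({e.i}, {e.j}) must have lambda = "
                    f"gamma~ = 0")
        return self

    def _check_well_posed(self) -> None:
        """Every compartment must be grounded through Dirichlet/Robin BCs,
        possibly via gamma-coupling to a grounded compartment."""
        grounded = {j for j, bc in self.pressure_bcs.items()
                    if bc.kind in ("robin", "dirichlet")}
        changed = True
        while changed:
            changed = False
            for e in self.edges:
                if e.gamma > 0 and ((e.i in grounded) != (e.j in grounded)):
                    grounded.update((e.i, e.j))
                    changed = True
        floating = [j for j in self.compartments if j not in grounded]
        if floating:
            raise ModelError(
                "pressure problem is singular: compartment(s) "
                f"{floating} have only Neumann data and no coupling path to "
                "a Dirichlet/Robin-grounded compartment")


def _resolve_edges(table: ParameterTable, pairs: list[tuple[str, str]]
                   ) -> list[Edge]:
    edges = []
    for (i, j) in pairs:
        c = table.get_pair(i, j)
        edges.append(Edge(i=i, j=j, kind=c.kind, gamma=c.gamma,
                          gamma_tilde=c.gamma_tilde, lam=c.lam,
                          sigma_osmotic=c.sigma_osmotic))
    return edges


def build_test_case(n: int, table: ParameterTable | None = None,
                    sas_model: str = "decay",
                    overrides: dict[str, PressureBC] | None = None
                    ) -> ModelSpec:
    """Build the ModelSpec of test case ``n`` (1, 2 or 3).

    ``overrides`` replaces the pressure BC of named compartments (used by
    scenario files and verification fixtures).
    """
    if n not in CASE_EDGES:
        raise ModelError(f"test case must be 1, 2 or 3, got {n!r}")
    if table is None:
        table = baseline_table(n)
    comps = table.compartments

    pressure_bcs: dict[str, PressureBC] = {}
    if n >= 2:
        pressure_bcs["e"] = PressureBC.robin(table.L_e_sas, table.p_sas)
        pressure_bcs["pa"] = PressureBC.robin(table.L_pvspial_pa,
                                              table.p_pvspial)
        pressure_bcs["pc"] = PressureBC.neumann(0.0)
        pressure_bcs["pv"] = PressureBC.dirichlet(table.p_pv_boundary)
    if n == 3:
        pressure_bcs["a"] = PressureBC.neumann(table.b_blood)
        pressure_bcs["c"] = PressureBC.neumann(0.0)
        pressure_bcs["v"] = PressureBC.dirichlet(table.p_v_boundary)
    if overrides:
        for tag, bc in overrides.items():
            if tag not in comps:
                raise ModelError(f"override for absent compartment {tag!r}")
            pressure_bcs[tag] = bc

    conc_mode = {j: ("sas_coupled" if j in ("pa", "pv", "e")
                     else "zero_total_flux") for j in comps}

    spec = ModelSpec(
        test_case=n,
        compartments=comps,
        edges=_resolve_edges(table, CASE_EDGES[n]),
        table=table,
        pressure_bcs=pressure_bcs,
        concentration_mode=conc_mode,
        sas_model=sas_model,
    )
    return spec.validate()


# ---------------------------------------------------------------------------
# Pointwise source terms
# ---------------------------------------------------------------------------

def _pressure_drive(edge: Edge, tag: str, pressures: dict[str, np.ndarray],
                    table: ParameterTable) -> np.ndarray:
    """(p_i - p_j) - sigma_ij (pi_i - pi_j) seen from compartment ``tag``=j."""
    other = edge.other(tag)
    try:
        p_i, p_j = pressures[other], pressures[tag]
    except KeyError as err:
        raise ModelError(f"missing pressure field for compartment "
                         f"{err.args[0]!r}") from None
    dpi = table.pi[other] - table.pi[tag]
    return (np.asarray(p_i) - np.asarray(p_j)) - edge.sigma_osmotic * dpi


def fluid_source(tag: str, pressures: dict[str, np.ndarray], spec: ModelSpec
                 ) -> np.ndarray:
    """Fluid exchange source r_j of compartment ``tag``, pointwise (1/s)."""
    phi = spec.table.phi[tag]
    out = np.zeros_like(np.asarray(pressures[tag], dtype=float))
    for edge in spec.edges_of(tag):
        out += edge.gamma * _pressure_drive(edge, tag, pressures, spec.table)
    return out / phi


def solute_source(tag: str, concentrations: dict[str, np.ndarray],
                  pressures: dict[str, np.ndarray], spec: ModelSpec
                  ) -> np.ndarray:
    """Solute exchange source s_j of compartment ``tag`` (conc / s)."""
    phi = spec.table.phi[tag]
    c_j = np.asarray(concentrations[tag], dtype=float)
    out = np.zeros_like(c_j)
    for edge in spec.edges_of(tag):
        other = edge.other(tag)
        try:
            c_i = np.asarray(concentrations[other])
        except KeyError:
            raise ModelError(f"missing concentration field for compartment "
                             f"{other!r}") from None
        out += edge.lam * (c_i - c_j)
        if edge.gamma_tilde != 0.0:
            drive = _pressure_drive(edge, tag, pressures, spec.table)
            out += 0.5 * (c_j + c_i) * edge.gamma_tilde * drive
    return out / phi
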