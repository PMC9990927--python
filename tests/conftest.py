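"""Shared fixtures: synthetic meshes and model specifications.

Meshes are session-scoped (generation is deterministic and read-only use
only); parameter tables are function-scoped copies because tests mutate
them.
"""

import numpy as np
import pytest

from glymphsim.geometry import synthetic_brain_mesh
from glymphsim.model import build_test_case
from glymphsim.params import baseline_table

BRAIN_VOLUME = 2313.0  # mm^3
SPHERE_RADIUS = (3.0 * BRAIN_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
D_STAR = 1.03e-4       # mm^2/s, effective inulin diffusion


@pytest.fixture(scope="session")
def sphere6():
    return synthetic_brain_mesh(BRAIN_VOLUME, "sphere", 6)


@pytest.fixture(scope="session")
def sphere8():
    return synthetic_brain_mesh(BRAIN_VOLUME, "sphere", 8)


@pytest.fixture(scope="session")
def sphere16():
    return synthetic_brain_mesh(BRAIN_VOLUME, "sphere", 16)


@pytest.fixture()
def table2():
    return baseline_table(2)


@pytest.fixture()
def table3():
    return baseline_table(3)


@pytest.fixture()
def spec2():
    return build_test_case(2)


@pytest.fixture()
def spec3():
    return build_test_case(3)


@pytest.fixture()
def injection_site():
    """Default off-centre injection ~4.5 mm under the sphere surface."""
    return (SPHERE_RADIUS - 4.5, 0.0, 0.0)


def two_compartment_fixture():
    """Smooth spherically-symmetric two-compartment verification problem.

    Couples a periarterial-like and an ECS-like network through the
    published gamma_pa,e = 2.19e-7 /(s Pa), with verification-grade
    permeabilities chosen so the pressure screening lengths are 3 and 4 mm
    (resolvable on coarse meshes; baseline permeabilities give micron-scale
    boundary layers no whole-organ mesh resolves).  Returns the 3-D
    ModelSpec together with the matching radial-oracle inputs.
    """
    from glymphsim.model import Edge, ModelSpec, PressureBC
    from glymphsim.oracles import RadialCompartment, RadialEdge
    from glymphsim.units import mmhg_to_pa

    gamma = 2.19e-7
    beta = {"pa": gamma * 3.0**2, "e": gamma * 4.0**2}   # kappa/mu
    p_pial = mmhg_to_pa(4.74)
    p_sas = mmhg_to_pa(3.26)
    conductance = 3.13e-7

    table = baseline_table(2)
    for j in ("pa", "e"):
        table.kappa[j] = beta[j] * table.mu[j]
    spec = ModelSpec(
        test_case=2, compartments=("pa", "e"),
        edges=[Edge("pa", "e", "membrane", gamma, 0.0, 0.0, 0.0)],
        table=table,
        pressure_bcs={"pa": PressureBC.dirichlet(p_pial),
                      "e": PressureBC.robin(conductance, p_sas)},
        concentration_mode={"pa": "sas_coupled", "e": "sas_coupled"},
    ).validate()

    oracle_comps = [
        RadialCompartment("pa", beta=beta["pa"], phi=table.phi["pa"],
                          bc=("dirichlet", p_pial)),
        RadialCompartment("e", beta=beta["e"], phi=table.phi["e"],
                          bc=("robin", conductance, p_sas)),
    ]
    oracle_edges = [RadialEdge(i="pa", j="e", gamma=gamma)]
    return spec, oracle_comps, oracle_edges, (p_sas, p_pial)
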