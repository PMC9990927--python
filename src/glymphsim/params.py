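"""Physical parameters of the multi-compartment brain-fluid model.

Single source of truth for the model constants: per-compartment fluid
properties (permeability, viscosity, porosity, effective diffusion, osmotic
pressure), per-pair exchange coefficients (hydraulic conductivity, surface
density, solute permeability, reflection coefficients and the derived
transfer rates gamma, gamma_tilde, lambda), and the scalar boundary/flow
constants.  Everything is stored in the coherent mm / s / Pa unit system of
:mod:`glymphsim.units`.

The seven compartments are tagged

    ``a``, ``c``, ``v``   arterial, capillary and venous blood,
    ``pa``, ``pc``, ``pv``  the perivascular spaces around them,
    ``e``                 the extracellular space (ECS).

Derivation helpers (``membrane_gamma``, ``flow_gamma``, ...) expose the
formulas the baseline coefficients were computed from; ``baseline_table``
returns the published baseline values verbatim, including the handful of
table entries whose printed value differs from the formula path in the last
digit (kept as printed for reproducibility).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .units import (
    ml_per_min_to_mm3_per_s,
    mmhg_to_pa,
    perfusion_to_mm3_per_s,
    ul_per_min_to_mm3_per_s,
)

__all__ = [
    "COMPARTMENTS",
    "BLOOD",
    "PVS",
    "ParameterError",
    "PairCoefficients",
    "ParameterTable",
    "effective_diffusion",
    "membrane_gamma",
    "flow_gamma",
    "gamma_tilde",
    "lambda_coeff",
    "kozeny_carman_factor",
    "pvs_sleep_factors",
    "csf_volume",
    "baseline_table",
    "apply_variation",
]

COMPARTMENTS: tuple[str, ...] = ("a", "c", "v", "pa", "pc", "pv", "e")
BLOOD: frozenset[str] = frozenset({"a", "c", "v"})
PVS: frozenset[str] = frozenset({"pa", "pc", "pv"})

CASE_COMPARTMENTS: dict[int, tuple[str, ...]] = {
    1: ("e",),
    2: ("pa", "pc", "pv", "e"),
    3: ("a", "c", "v", "pa", "pc", "pv", "e"),
}


class ParameterError(ValueError):
    """A parameter violates its physical domain, or a name is unknown."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# ---------------------------------------------------------------------------
# Derivation formulas
# ---------------------------------------------------------------------------

def effective_diffusion(d_free: float, tortuosity: float) -> float:
    """Effective diffusion D* = D_free / lambda^2 (tortuosity-hindered)."""
    _check(d_free >= 0, f"free diffusion must be >= 0, got {d_free}")
    _check(tortuosity >= 1, f"tortuosity must be >= 1, got {tortuosity}")
    return d_free / tortuosity**2


def membrane_gamma(conductivity: float, s_over_v: float) -> float:
    """Fluid transfer coefficient gamma = L * (S/|Omega|) of a membrane.

    Parameters are the membrane hydraulic conductivity L in mm/(s Pa) and the
    membrane surface density S/|Omega| in 1/mm; the result is in 1/(s Pa).
    """
    _check(conductivity >= 0, "hydraulic conductivity must be >= 0")
    _check(s_over_v >= 0, "surface density must be >= 0")
    return conductivity * s_over_v


def flow_gamma(q_flow: float, dp: float, volume: float) -> float:
    """Transfer coefficient of a branching connection, gamma = Q/(dp |Omega|).

    Derived from a known total flow rate Q (mm^3/s) through the connection,
    the pressure drop dp (Pa) driving it, and the tissue volume (mm^3).
    """
    _check(dp > 0, f"pressure drop must be > 0, got {dp}")
    _check(volume > 0, f"volume must be > 0, got {volume}")
    _check(q_flow >= 0, f"flow must be >= 0, got {q_flow}")
    return q_flow / (dp * volume)


def gamma_tilde(gamma: float, sigma_reflect: float) -> float:
    """Advective solute transfer coefficient gamma~ = gamma (1 - sigma_reflect)."""
    _check(0.0 <= sigma_reflect <= 1.0,
           f"solvent-drag reflection must be in [0, 1], got {sigma_reflect}")
    return gamma * (1.0 - sigma_reflect)


def lambda_coeff(permeability: float, s_over_v: float) -> float:
    """Diffusive solute transfer coefficient lambda = P * (S/|Omega|) in 1/s."""
    _check(permeability >= 0, "membrane solute permeability must be >= 0")
    _check(s_over_v >= 0, "surface density must be >= 0")
    return permeability * s_over_v


def kozeny_carman_factor(phi_old: float, phi_new: float) -> float:
    """Permeability ratio implied by a porosity change, Kozeny-Carman scaling.

    kappa ~ phi^3 / (1 - phi)^2, so the ratio is
    [phi_new^3/(1-phi_new)^2] / [phi_old^3/(1-phi_old)^2].
    """
    for phi in (phi_old, phi_new):
        _check(0.0 < phi < 1.0, f"porosity must be in (0, 1), got {phi}")
    def kc(phi: float) -> float:
        return phi**3 / (1.0 - phi) ** 2
    return kc(phi_new) / kc(phi_old)


def pvs_sleep_factors(c_phi: float) -> tuple[float, float]:
    """Porosity and permeability factors for PVS dilation during sleep.

    Assuming Poiseuille-like flow in the perivascular annulus, a porosity
    increase by C_phi implies a permeability increase by C_phi^2.
    """
    _check(c_phi > 0, f"C_phi must be > 0, got {c_phi}")
    return c_phi, c_phi**2


def csf_volume(brain_volume: float, csf_fraction_of_icv: float) -> float:
    """SAS CSF volume from the CSF fraction f of total intracranial volume.

    With ICV = brain + CSF, a fraction f of ICV corresponds to
    V_CSF = brain_volume * f / (1 - f).
    """
    _check(0.0 <= csf_fraction_of_icv < 1.0,
           f"CSF fraction must be in [0, 1), got {csf_fraction_of_icv}")
    f = csf_fraction_of_icv
    return brain_volume * f / (1.0 - f)


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

Pair = tuple[str, str]


def pair_key(i: str, j: str) -> Pair:
    """Canonical (sorted) key of an unordered compartment pair."""
    if i == j:
        raise ParameterError(f"pair must join two distinct compartments, got ({i}, {j})")
    for tag in (i, j):
        if tag not in COMPARTMENTS:
            raise ParameterError(f"unknown compartment tag {tag!r}")
    return (i, j) if i < j else (j, i)


@dataclass
class PairCoefficients:
    """Exchange coefficients of one compartment pair.

    ``kind`` is "membrane" (transfer across a separating membrane) or
    "branching" (direct connection along a vessel tree).  Branching
    connections carry no membrane, hence P = 0 and sigma_reflect = 1.
    """

    kind: str = "membrane"
    conductivity: float = 0.0      # L_{i,j}, mm/(s Pa)
    s_over_v: float = 0.0          # S_{i,j}/|Omega|, 1/mm
    permeability: float = 0.0      # P_{i,j}, mm/s
    sigma_osmotic: float = 0.0     # osmotic reflection in the fluid equation
    sigma_reflect: float = 1.0     # solvent-drag reflection for the solute
    gamma: float = 0.0             # 1/(s Pa)
    lam: float = 0.0               # 1/s

    @property
    def gamma_tilde(self) -> float:
        return gamma_tilde(self.gamma, self.sigma_reflect)

    def validate(self) -> None:
        _check(self.kind in ("membrane", "branching"),
               f"unknown pair kind {self.kind!r}")
        for name in ("conductivity", "s_over_v", "permeability", "gamma", "lam"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("sigma_osmotic", "sigma_reflect"):
            _check(0.0 <= getattr(self, name) <= 1.0, f"{name} must be in [0, 1]")
        if self.kind == "branching":
            _check(self.permeability == 0.0, "branching pairs have P = 0")
            _check(self.sigma_reflect == 1.0, "branching pairs have sigma_reflect = 1")


@dataclass
class ParameterTable:
    """All constants of one model configuration, in mm / s / Pa units.

    ``pairs`` is a symmetric sparse map keyed by the canonical unordered
    pair; a pair that is absent has exactly zero coupling.
    """

    compartments: tuple[str, ...]
    kappa: dict[str, float]            # mm^2
    mu: dict[str, float]               # Pa s
    phi: dict[str, float]              # -
    diffusion: dict[str, float]        # D*_j, mm^2/s
    pi: dict[str, float]               # osmotic pressure, Pa
    pairs: dict[Pair, PairCoefficients] = field(default_factory=dict)

    # scalars (mm^3/s, Pa, ... as annotated)
    d_free: float = 2.98e-4            # mm^2/s
    tortuosity: float = 1.7
    b_flow: float = 0.0                # cerebral blood flow, mm^3/s
    b_blood: float = 0.0               # boundary arterial inflow, mm^3/s
    q_csf: float = 0.0                 # CSF production, mm^3/s
    dp_c_a: float = 0.0                # Pa
    dp_v_c: float = 0.0
    dp_pa_pc: float = 0.0
    dp_pc_pv: float = 0.0
    p_sas: float = 0.0                 # Pa
    p_pvspial: float = 0.0
    p_pv_boundary: float = 0.0
    p_v_boundary: float = 0.0
    L_e_sas: float = 0.0               # boundary conductance of the pial ECS surface
    L_pvspial_pa: float = 0.0          # boundary conductance pial PVS -> pa
    alpha: float | None = None         # SAS absorption rate, 1/s; None = Q_CSF/V_CSF
    v_csf_fraction: float = 0.12       # V_CSF = fraction * |Omega|
    c_phi: float = 4.0                 # PVS sleep porosity factor
    brain_mass_g: float = 2.0

    # ------------------------------------------------------------------
    def get_pair(self, i: str, j: str) -> PairCoefficients:
        """Coefficients of the (i, j) pair; zero coupling if not connected."""
        return self.pairs.get(pair_key(i, j), PairCoefficients())

    def connected(self, i: str, j: str) -> bool:
        return pair_key(i, j) in self.pairs

    def gamma(self, i: str, j: str) -> float:
        return self.get_pair(i, j).gamma

    def gamma_tilde(self, i: str, j: str) -> float:
        return self.get_pair(i, j).gamma_tilde

    def lam(self, i: str, j: str) -> float:
        return self.get_pair(i, j).lam

    def sas_alpha(self, brain_volume: float) -> float:
        """SAS absorption rate; defaults to CSF turnover Q_CSF / V_CSF."""
        if self.alpha is not None:
            return self.alpha
        return self.q_csf / self.csf_volume(brain_volume)

    def csf_volume(self, brain_volume: float) -> float:
        return self.v_csf_fraction * brain_volume

    def copy(self) -> "ParameterTable":
        return copy.deepcopy(self)

    def validate(self) -> None:
        for j in self.compartments:
            _check(j in COMPARTMENTS, f"unknown compartment tag {j!r}")
            _check(self.kappa[j] >= 0, f"kappa_{j} must be >= 0")
            _check(self.mu[j] > 0, f"mu_{j} must be > 0")
            _check(0.0 <= self.phi[j] < 1.0, f"phi_{j} must be in [0, 1)")
            _check(self.diffusion[j] >= 0, f"D*_{j} must be >= 0")
            _check(self.pi[j] >= 0, f"pi_{j} must be >= 0")
        for (i, j), coeffs in self.pairs.items():
            _check(i in self.compartments and j in self.compartments,
                   f"pair ({i}, {j}) references an absent compartment")
            coeffs.validate()
        for name in ("b_flow", "b_blood", "q_csf", "L_e_sas", "L_pvspial_pa"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        _check(0.0 <= self.v_csf_fraction, "v_csf_fraction must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format audit report of every resolved coefficient."""
        rows: list[dict[str, object]] = []
        for j in self.compartments:
            rows += [
                {"parameter": f"kappa_{j}", "value": self.kappa[j], "unit": "mm^2"},
                {"parameter": f"mu_{j}", "value": self.mu[j], "unit": "Pa s"},
                {"parameter": f"phi_{j}", "value": self.phi[j], "unit": "-"},
                {"parameter": f"D_{j}", "value": self.diffusion[j], "unit": "mm^2/s"},
                {"parameter": f"pi_{j}", "value": self.pi[j], "unit": "Pa"},
            ]
        for (i, j), c in sorted(self.pairs.items()):
            tag = f"{i},{j}"
            rows += [
                {"parameter": f"gamma_{tag}", "value": c.gamma, "unit": "1/(s Pa)"},
                {"parameter": f"gamma_tilde_{tag}", "value": c.gamma_tilde,
                 "unit": "1/(s Pa)"},
                {"parameter": f"lambda_{tag}", "value": c.lam, "unit": "1/s"},
                {"parameter": f"sigma_reflect_{tag}", "value": c.sigma_reflect,
                 "unit": "-"},
                {"parameter": f"sigma_osmotic_{tag}", "value": c.sigma_osmotic,
                 "unit": "-"},
            ]
        for name, unit in [
            ("d_free", "mm^2/s"), ("tortuosity", "-"), ("b_flow", "mm^3/s"),
            ("b_blood", "mm^3/s"), ("q_csf", "mm^3/s"), ("p_sas", "Pa"),
            ("p_pvspial", "Pa"), ("p_pv_boundary", "Pa"), ("p_v_boundary", "Pa"),
            ("L_e_sas", "mm/(s Pa)"), ("L_pvspial_pa", "mm/(s Pa)"),
            ("v_csf_fraction", "-"), ("c_phi", "-"),
        ]:
            rows.append({"parameter": name, "value": getattr(self, name), "unit": unit})
        rows.append({"parameter": "alpha", "unit": "1/s",
                     "value": float("nan") if self.alpha is None else self.alpha})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Baseline values
# ---------------------------------------------------------------------------

_MU_BLOOD = 2.67e-3
_MU_CSF = 7.0e-4
_D_STAR = 1.03e-4

_KAPPA = {"a": 3.30e-6, "v": 6.59e-6, "c": 8.8e-9,
          "pa": 1.0e-11, "pv": 6.51e-9, "pc": 3.54e-13, "e": 2.0e-11}
_PHI = {"e": 0.14, "a": 0.0071, "c": 0.011, "v": 0.016,
        "pa": 0.0021, "pc": 0.0033, "pv": 0.0046}

_PI_BLOOD_MMHG = 20.0
_PI_TISSUE_FACTOR = 0.2

# Printed surface densities (1/mm): capillaries 9, arteries and veins 3.
_S_OVER_V = {"a": 3.0, "c": 9.0, "v": 3.0}

# Membrane hydraulic conductivities blood <-> ECS, mm/(s Pa).
_L_BLOOD_ECS = {"a": 9.1e-10, "c": 1.0e-10, "v": 2.0e-11}

# AEF membrane solute permeabilities for inulin, mm/s.
_P_AEF = {"pa": 1.2e-3, "pc": 4.1e-4, "pv": 1.2e-3}

_SIGMA_REFLECT_INULIN = 0.2


def _baseline_pairs() -> dict[Pair, PairCoefficients]:
    """All published pair coefficients of the 7-compartment configuration."""
    pairs: dict[Pair, PairCoefficients] = {}

    def add(i: str, j: str, **kw) -> None:
        pairs[pair_key(i, j)] = PairCoefficients(**kw)

    # Blood <-> ECS membranes (BBB; impermeable and fully reflecting to inulin).
    add("a", "e", kind="membrane", conductivity=_L_BLOOD_ECS["a"],
        s_over_v=_S_OVER_V["a"], gamma=2.7e-9, sigma_osmotic=1.0)
    add("c", "e", kind="membrane", conductivity=_L_BLOOD_ECS["c"],
        s_over_v=_S_OVER_V["c"], gamma=9.0e-10, sigma_osmotic=1.0)
    add("v", "e", kind="membrane", conductivity=_L_BLOOD_ECS["v"],
        s_over_v=_S_OVER_V["v"], gamma=6.0e-11, sigma_osmotic=1.0)

    # PVS <-> ECS astrocyte-endfeet membranes (permeable to inulin).
    add("pa", "e", kind="membrane", gamma=2.19e-7, s_over_v=_S_OVER_V["a"],
        permeability=_P_AEF["pa"], lam=3.70e-3,
        sigma_reflect=_SIGMA_REFLECT_INULIN)
    add("pc", "e", kind="membrane", gamma=9.20e-9, s_over_v=_S_OVER_V["c"],
        permeability=_P_AEF["pc"], lam=3.70e-3,
        sigma_reflect=_SIGMA_REFLECT_INULIN)
    add("pv", "e", kind="membrane", gamma=1.95e-7, s_over_v=_S_OVER_V["v"],
        permeability=_P_AEF["pv"], lam=3.72e-3,
        sigma_reflect=_SIGMA_REFLECT_INULIN)

    # Blood <-> PVS vessel-wall membranes (BBB).
    add("a", "pa", kind="membrane", gamma=2.76e-9, sigma_osmotic=1.0)
    add("c", "pc", kind="membrane", gamma=9.98e-10, sigma_osmotic=1.0)
    add("v", "pv", kind="membrane", gamma=6.00e-11, sigma_osmotic=1.0)

    # Vessel-tree branching connections (no membrane).
    add("a", "c", kind="branching", gamma=3.14e-6)
    add("c", "v", kind="branching", gamma=9.65e-6)
    add("pa", "pc", kind="branching", gamma=1.83e-7)
    add("pc", "pv", kind="branching", gamma=7.31e-7)

    return pairs


_VARIANTS = ("baseline", "sleep_ecs", "sleep_ecs_pvs")


def baseline_table(test_case: int = 2, variant: str = "baseline",
                   overrides: dict[str, float] | None = None) -> ParameterTable:
    """Published baseline parameters restricted to one test case.

    ``test_case`` 1 keeps only the ECS, 2 the four CSF/ISF compartments, and
    3 all seven.  ``variant`` applies the sleep scalings: ``sleep_ecs`` raises
    the ECS porosity 0.14 -> 0.23 with Kozeny-Carman permeability scaling;
    ``sleep_ecs_pvs`` additionally dilates every PVS compartment by C_phi = 4
    (porosity x4, permeability x16).  ``overrides`` multiplicatively rescales
    named parameters via :func:`apply_variation` semantics with absolute
    values (``{"p_sas": value_in_Pa}`` sets, not scales).
    """
    if test_case not in CASE_COMPARTMENTS:
        raise ParameterError(f"test case must be 1, 2 or 3, got {test_case!r}")
    if variant not in _VARIANTS:
        raise ParameterError(
            f"unknown variant {variant!r}; expected one of {_VARIANTS}")

    comps = CASE_COMPARTMENTS[test_case]
    pi_tissue = mmhg_to_pa(_PI_BLOOD_MMHG * _PI_TISSUE_FACTOR)
    pi_blood = mmhg_to_pa(_PI_BLOOD_MMHG)

    table = ParameterTable(
        compartments=comps,
        kappa={j: _KAPPA[j] for j in comps},
        mu={j: (_MU_BLOOD if j in BLOOD else _MU_CSF) for j in comps},
        phi={j: _PHI[j] for j in comps},
        diffusion={j: _D_STAR for j in comps},
        pi={j: (pi_blood if j in BLOOD else pi_tissue) for j in comps},
        pairs={key: c for key, c in _baseline_pairs().items()
               if key[0] in comps and key[1] in comps},
        b_flow=perfusion_to_mm3_per_s(116.0, 2.0),
        b_blood=ml_per_min_to_mm3_per_s(2.32),
        q_csf=ul_per_min_to_mm3_per_s(3.38),
        dp_c_a=mmhg_to_pa(40.0),
        dp_v_c=mmhg_to_pa(13.0),
        dp_pa_pc=mmhg_to_pa(1.0),
        dp_pc_pv=mmhg_to_pa(0.25),
        p_sas=mmhg_to_pa(3.26),
        p_pvspial=mmhg_to_pa(4.74),
        p_pv_boundary=mmhg_to_pa(3.26),
        p_v_boundary=mmhg_to_pa(7.0),
        L_e_sas=3.13e-7,
        L_pvspial_pa=1.25e-6,
    )

    if variant in ("sleep_ecs", "sleep_ecs_pvs"):
        phi_awake, phi_sleep = 0.14, 0.23
        table.kappa["e"] *= kozeny_carman_factor(phi_awake, phi_sleep)
        table.phi["e"] = phi_sleep
    if variant == "sleep_ecs_pvs":
        fac_phi, fac_kappa = pvs_sleep_factors(table.c_phi)
        for j in PVS:
            if j in table.phi:
                table.phi[j] *= fac_phi
                table.kappa[j] *= fac_kappa

    if overrides:
        for name, value in overrides.items():
            _set_parameter(table, name, value)

    table.validate()
    return table


# ---------------------------------------------------------------------------
# Variations (sensitivity analysis)
# ---------------------------------------------------------------------------

# Canonical ascii names plus the symbols the sensitivity table prints.
_ALIASES = {
    "κ_e": "kappa_e", "κ_pa": "kappa_pa", "κ_pc": "kappa_pc",
    "p_SAS": "p_sas", "P_{pa,e}": "P_pa_e", "P_pa,e": "P_pa_e",
    "γ_{pa,a}": "gamma_pa_a", "γ_pa,a": "gamma_pa_a",
    "D*": "D", "D_star": "D", "φ_pa": "phi_pa",
}


def _canonical_name(name: str) -> str:
    return _ALIASES.get(name, name)


def _set_parameter(table: ParameterTable, name: str, value: float) -> None:
    """Absolute override of a named parameter (used by config files)."""
    name = _canonical_name(name)
    if name.startswith("kappa_") and name[6:] in table.kappa:
        table.kappa[name[6:]] = value
    elif name.startswith("phi_") and name[4:] in table.phi:
        table.phi[name[4:]] = value
    elif name == "D":
        for j in table.diffusion:
            table.diffusion[j] = value
    elif name in ("p_sas", "p_pvspial", "p_pv_boundary", "p_v_boundary",
                  "L_e_sas", "L_pvspial_pa", "alpha", "v_csf_fraction",
                  "c_phi", "b_blood", "b_flow", "q_csf"):
        setattr(table, name, value)
    else:
        raise ParameterError(f"unknown parameter name {name!r}")


def apply_variation(table: ParameterTable, name: str, factor: float) -> ParameterTable:
    """Return a copy with one named parameter scaled by ``factor``.

    Supports the sensitivity-study set (kappa_e, kappa_pa, kappa_pc, p_sas,
    P_pa_e, gamma_pa_a, D, phi_pa) plus any ``kappa_<j>`` / ``phi_<j>`` key.
    Coefficients derived from the varied one are rescaled consistently:
    varying a membrane permeability P rescales the pair's lambda, and varying
    a gamma rescales the pair's gamma_tilde (implicitly, via gamma).
    """
    _check(factor > 0, f"variation factor must be > 0, got {factor}")
    new = table.copy()
    name = _canonical_name(name)

    if name.startswith("kappa_") and name[6:] in new.kappa:
        new.kappa[name[6:]] *= factor
    elif name.startswith("phi_") and name[4:] in new.phi:
        new.phi[name[4:]] *= factor
    elif name == "p_sas":
        new.p_sas *= factor
    elif name == "D":
        for j in new.diffusion:
            new.diffusion[j] *= factor
    elif name == "P_pa_e":
        coeffs = new.pairs[pair_key("pa", "e")]
        coeffs.permeability *= factor
        coeffs.lam *= factor
    elif name == "gamma_pa_a":
        new.pairs[pair_key("a", "pa")].gamma *= factor
    else:
        raise ParameterError(f"unknown variation parameter {name!r}")

    new.validate()
    return new
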