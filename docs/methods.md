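# Methods

This note documents the model equations as implemented, the unit and
bookkeeping conventions, the numerical choices, what the synthetic
surrogate geometry does and does not emulate, and the known limitations.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

### Compartments and exchange

The brain tissue Ω (volume |Ω|) hosts up to seven interpenetrating fluid
networks, present at every point: arterial, capillary and venous blood
(`a`, `c`, `v`), their perivascular spaces (`pa`, `pc`, `pv`) and the
extracellular space (`e`). Each network j has a porosity φⱼ (volume
fraction), permeability κⱼ (mm²), fluid viscosity μⱼ (Pa·s), effective
tracer diffusivity Dⱼ* (mm²/s) and osmotic pressure πⱼ (Pa).

Networks are connected either across a membrane (vessel wall, astrocyte
endfeet) or by direct vessel branching (arteries → capillaries → veins and
the analogous perivascular tree). Each connection carries three transfer
coefficients:

* fluid: γ = L·S/|Ω| for membranes (hydraulic conductivity × surface
  density) or γ = Q/(Δp·|Ω|) for branching (a known organ-scale flow over
  its driving pressure drop);
* diffusive solute: λ = P·S/|Ω| (membrane solute permeability × surface
  density); zero for branching connections and for every blood-facing
  membrane, because inulin does not cross the blood–brain barrier;
* advective solute (solvent drag): γ̃ = γ(1 − σ_reflect) with
  σ_reflect = 0.2 at the endfeet membranes and 1 (full rejection)
  elsewhere.

Osmotic effects act only across blood-facing membranes (σ_osmotic = 1
there, 0 between CSF/ISF spaces, whose osmotic pressures are equal anyway);
blood carries π = 20 mmHg and the extravascular spaces 20 % of that.

### Pressure problem

The steady, rigid-matrix (static MPET) fluid balance solved for each
network is

    −∇·( (κⱼ/μⱼ) ∇pⱼ ) = Σᵢ γⱼᵢ [ (pᵢ − pⱼ) − σᵢⱼ (πᵢ − πⱼ) ].

Two bookkeeping conventions needed fixing where the source texts are
ambiguous, and both are resolved in favour of internal consistency with
how the coefficients were derived:

* The divergence acts on the Darcy (superficial) flux v = −(κ/μ)∇p. With
  this mobility the reported pore velocity u = v/φ = −κ/(φμ)∇p is exactly
  the flux per unit pore area, and the boundary flux ∮(−κ/μ)∇p·ν is the
  operator's natural flux.
* The exchange source carries no 1/φ prefactor: γ values are defined from
  *total* flows over pressure drops and tissue volume, so the lumped
  circuit (arterial inflow B_blood ≈ 2.32 mL/min passing a→c at a 40 mmHg
  drop, CSF production through the perivascular tree) only closes without
  it. The porosity-normalized pointwise source r_j = (1/φⱼ)Σγ(…) remains
  available (`glymphsim.model.fluid_source`) for audit, and both the Darcy
  and the φ-weighted boundary-flux conventions are reported.

Boundary conditions (per compartment, on the whole surface): Robin
outflux = L(p − p_ext) for `e` (to the SAS at 3.26 mmHg through
L_e,SAS = 3.13·10⁻⁷) and `pa` (to the pial periarterial CSF at 4.74 mmHg
through L_PVSpial,pa = 1.25·10⁻⁶); homogeneous Neumann for `pc` and `c`;
Dirichlet for `pv` (3.26 mmHg) and `v` (7.0 mmHg); uniform Neumann *influx*
B_blood/|∂Ω| for `a`. The Robin/Neumann signs are the coercive, physical
ones (fluid flows down the pressure difference; arterial blood flows in).

The monolithic system over all compartments is symmetric positive definite.
It is solved either by sparse LU (with symmetric diagonal equilibration and
minimum-degree ordering — the raw blocks span ~10 orders of magnitude,
which otherwise destroys threshold pivoting) or, above ~12 000 unknowns,
by Jacobi-preconditioned conjugate gradients to a relative residual well
below 10⁻⁸. The assembled residual is verified after every solve.

### Transport problem

The microscopic (pore-fluid) concentration cⱼ advects with the pore
velocity uⱼ and diffuses with Dⱼ*:

    ∂cⱼ/∂t + ∇·(cⱼ uⱼ) − Dⱼ*Δcⱼ = sⱼ,
    sⱼ = (1/φⱼ) Σᵢ [ λⱼᵢ(cᵢ − cⱼ) + ((cᵢ+cⱼ)/2) γ̃ⱼᵢ (pᵢ − pⱼ − σᵢⱼΔπ) ].

Here the 1/φⱼ *is* kept: λ and γ̃ transfer tracer mass per unit tissue
volume, and dividing by φⱼ converts that into a rate of the microscopic
concentration. The φ-weighted total mass φⱼcⱼ is what all mass accounting
uses. The advective inter-compartment term uses the arithmetic mean
(cᵢ+cⱼ)/2 with no upwinding. The effective diffusivity
D* = D_free/λ_tort² = 1.03·10⁻⁴ mm²/s (free inulin diffusion through
tortuosity 1.7) is used in every compartment; only the ECS value is
physiologically constrained, but the blood compartments never carry tracer
(the BBB blocks all solute paths into them, and their concentration blocks
are exactly decoupled — they remain identically zero), and the CSF spaces
are assumed similarly hindered.

Tracer boundary conditions: `pa`, `pv` and `e` communicate with the SAS
and carry the Dirichlet value g(t); all other compartments carry a weak
zero-total-flux wall (the convective and diffusive boundary integrals are
dropped from the weak form).

### SAS reservoir

The SAS is well mixed with volume V_CSF = 0.12·|Ω|. Its concentration g(t)
follows dg/dt = −αg + F/V_CSF, where F is the brain-to-SAS mass flux and α
the CSF absorption rate. F is evaluated from the discrete mass balance of
the transport step just taken (not by surface quadrature), which makes the
α = 0 limit reproduce the strict conservation model *exactly* and closes
the mass ledger at every step. Three models:

* `homogeneous` — g ≡ 0 (instantaneous clearance from the CSF);
* `conservation` — g = (N₀ − intracranial mass)/V_CSF;
* `decay` — backward-Euler integration of the ODE; α defaults to the CSF
  turnover rate Q_CSF/V_CSF ≈ 2.0·10⁻⁴ s⁻¹ (no measured value exists for
  this lumped absorption rate, and turnover is its natural scale);
  configurable.

g enters the Dirichlet data lagged by one step; the lag error is below the
time-discretization error at the default Δt (verified by the Δt-halving
test).

### Initial condition

A Gaussian bolus c_e(0) = C⁰ exp(−|x−s|²/σ²) with σ = 1 mm, scaled so the
φ-weighted integral equals the injected amount N₀, then set to zero on
boundary nodes to conform to the boundary data (for the default interior
injection the projection removes < 10⁻⁶ of the mass; no re-normalization
is applied, and all relative quantities divide by the *discrete* t = 0
mass). Exact quadrature places 95.4 % of this profile within 2 mm of the
injection site. The default injection site lies 4.5 mm beneath the surface
(for the sphere surrogate, on the +x axis), matching the depth of the
atlas-coordinate site used with real brain meshes; it is configurable.

## Discretization

Continuous piecewise-linear (P1) finite elements on tetrahedra for every
field; implicit (backward) Euler in time with Δt = 1 min over T = 360 min
by default. All compartments are advanced in one monolithic linear solve
per step; the matrix is constant in time, so its factorization is reused
across all 360 steps. Consistent mass matrices are the default, with an
optional mass-lumping flag. No convective stabilization is applied; the
scheme produces small negative concentration undershoots near the tail of
the spreading Gaussian (about 3·10⁻⁵ of the initial peak at resolution 32,
~10⁻² at resolution 16, decaying in time), which integrated quantities are
insensitive to.

## Geometry

Meshes are tetrahedral volumes in millimetres, read from Gmsh `.msh`
(ASCII 2.2/4.1), VTK `.vtu` (ASCII) or XDMF, and validated (positive cell
volumes, closed orientable boundary). The synthetic surrogate maps a
structured cube lattice onto a ball (or ellipsoid) of prescribed volume —
2313 mm³, radius 8.20 mm, by default — via the max-norm radial map, with
each hexahedron split into six conforming tetrahedra. Its volume error is
~1.9 % at resolution 8 (cells across the diameter), 0.47 % at 16 and
0.12 % at 32, converging at second order.

What the surrogate emulates: the correct tissue volume, surface area scale,
parameter set and all model couplings. What it does not: the thin, folded
geometry of a real brain, where every point lies within a few millimetres
of a CSF space. Clearance on the surrogate is therefore systematically
slower than on an atlas-derived mesh (most of the sphere is ~8 mm from the
surface), and passing tests on it validate *identities, convergence and
model orderings* — conservation, decoupling, boundary-model ordering,
blood-driven speed-up — not the absolute clearance fractions of a real rat
brain. Scenario files accept an external brain mesh for the latter.

Sampling regions for "measurement sample" studies are axis-aligned cubes
resolved to the set of cells whose centroid lies inside (no partial-cell
clipping; convergent under refinement).

## Verification oracles

Two independent solution paths, sharing no assembly code with the solvers:

* diffusion in a ball with homogeneous Dirichlet data — eigenfunction
  series in sin(nπr/R)/r with quadrature coefficients (truncated when the
  term magnitude falls below 10⁻¹⁰; the Gaussian spectrum decays
  super-exponentially), cross-checked against a conservative radial
  finite-volume operator integrated exactly in time through a symmetric
  tridiagonal eigendecomposition (the two agree to ~10⁻⁷);
* spherically symmetric coupled Darcy systems — second-order radial
  finite-volume discretization with optional Richardson extrapolation.

The two-compartment verification problem couples a periarterial-like and
an ECS-like network through the baseline γ_pa,e = 2.19·10⁻⁷ (s·Pa)⁻¹ but
uses verification-grade mobilities giving pressure screening lengths
√(β/γ) of 3 and 4 mm. This is deliberate: with baseline permeabilities the
exact solution has micron-scale boundary layers that no organ-scale mesh
resolves (the production meshes are under-resolved in exactly the same
way), so a pointwise comparison against a resolved oracle is only
meaningful on a configuration whose fields the meshes can represent. On it,
the 3-D solver converges at the expected second order with sub-percent
profile and flux errors.

## Problem sizes and defaults

Default production resolution 16 (≈ 4 900 vertices, 25 000 cells) for
multi-compartment runs and sensitivity sweeps, resolution 32 for the
diffusion-validation study; Δt = 60 s, T = 21 600 s. These sizes keep a
full 360-step seven-compartment run around a minute on one CPU while
leaving the discretization errors (mesh and time) at or below the percent
level for integrated quantities, as the refinement tests demonstrate.

## Known limitations

* Rigid matrix: no poroelastic displacement, no time-dependent porosity
  (vasomotion), no oscillatory drivers.
* The homogenized continuum description is questionable for arterioles and
  venules, whose spacing is not far below the organ scale; a 1D–3D vessel
  model would be the refinement.
* No stabilized transport discretization; strongly convection-dominated
  regimes (far beyond the baseline parameters) would need SUPG or upwinding
  rather than mesh refinement alone.
* The SAS is a single well-mixed reservoir; no spatial CSF dynamics outside
  the parenchyma.
* Endogenous production/clearance of solutes is not modelled; the tracer
  enters only through the initial bolus.
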