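# glymphsim

Multi-compartment simulation of fluid flow and solute clearance in brain
tissue, at the scale of a whole rat brain. The package models the
glymphatic system — the proposed pathway in which cerebrospinal fluid (CSF)
enters the tissue along periarterial spaces, exchanges with interstitial
fluid across the astrocyte endfeet, and leaves along perivenous spaces —
and uses it to simulate the clearance of an intraparenchymally injected
tracer (¹⁴C-inulin, a ~5 kDa polysaccharide that does not cross the
blood–brain barrier).

It is aimed at researchers in brain fluid dynamics who want an executable,
parameter-transparent version of the static multiple-network poroelastic
(MPET) description of brain fluids: every physiological constant is a named,
unit-checked entry in a parameter table, and every simulation runs either on
a standard tetrahedral mesh (Gmsh/VTU/XDMF) or on a built-in synthetic
brain-surrogate mesh, so no data download is ever required.

## Model

Up to seven fluid networks coexist at every point of the domain Ω: arterial,
capillary and venous blood (`a`, `c`, `v`), the perivascular spaces around
them (`pa`, `pc`, `pv`), and the extracellular space (`e`, porosity φₑ).
Steady Darcy pressures are coupled through membrane and vessel-branching
exchange,

    −∇·( (κⱼ/μⱼ) ∇pⱼ ) = Σᵢ γⱼᵢ [ (pᵢ − pⱼ) − σᵢⱼ (πᵢ − πⱼ) ],

with γ the fluid transfer coefficients (membrane: γ = L·S/|Ω|; branching:
γ = Q/(Δp·|Ω|)), σ the osmotic reflection of the blood-facing membranes and
π the osmotic pressures. The tracer concentration in each network obeys an
implicit-Euler convection–diffusion equation with pore velocity
uⱼ = −κⱼ/(φⱼμⱼ)∇pⱼ,

    ∂cⱼ/∂t + ∇·(cⱼ uⱼ) − Dⱼ*Δcⱼ = sⱼ,
    sⱼ = (1/φⱼ) Σᵢ [ λⱼᵢ(cᵢ − cⱼ) + ((cᵢ+cⱼ)/2) γ̃ⱼᵢ (pᵢ − pⱼ − σᵢⱼΔπ) ],

where λ = P·S/|Ω| is the diffusive membrane transfer, γ̃ = γ(1 − σ_reflect)
the solvent-drag transfer, and D* = D_free/λ_tort² the tortuosity-hindered
diffusion. The subarachnoid space (SAS) is a well-mixed reservoir whose
concentration g(t) feeds back as a Dirichlet boundary value; three SAS
models are available (instantaneous clearance, strict conservation, and
first-order absorption at rate α).

Three standard configurations ("test cases") are built in: pure ECS
diffusion (1), the four CSF/ISF compartments (2), and the full seven
networks with leaky blood vessels (3).

## Worked example

```python
import glymphsim as gs

mesh = gs.synthetic_brain_mesh(volume=2313.0, shape="sphere", resolution=16)
spec = gs.build_test_case(2, sas_model="decay")     # 4 compartments
result = gs.run_simulation(
    spec, mesh,
    gs.InjectionSpec(centre=(3.70, 0.0, 0.0), sigma=1.0, n0=1.0),
    gs.SimulationConfig(dt=60.0, t_end=21600.0))    # 360 one-minute steps

from glymphsim.quantities import rate_constant
print(f"remaining after 6 h: {result.c_tot[-1]:.3f}")
print(f"rate constant: {rate_constant(result.times_min, result.c_tot):.5f}/min")
```

prints (resolution-16 sphere surrogate, baseline parameters)

```
remaining after 6 h: 0.913
rate constant: 0.00025/min
```

i.e. 91% of the injected tracer is still inside the surrogate brain after
six hours under the absorption ("decay") boundary model. The surrogate
sphere is geometrically much thicker than a real rat brain (every point of
real cortex is within a few millimetres of a CSF surface), so clearance on
it is slower than on an atlas-derived mesh; the *relative* behaviour of the
models is preserved — e.g. the seven-compartment model clears several times
faster (final mass 0.38, rate 0.0027/min on the same mesh) because blood
filtration reverses the perivascular flow into an outflow route.

The same run from the shell:

```bash
glymph simulate --scenario case2_baseline --out run/
glymph sensitivity --scenario case2_baseline -p D -p kappa_e --out sweep.csv
glymph params report --case 2
glymph mesh make --volume 2313 --resolution 16 -o brain_surrogate.msh
glymph model describe --case 3
```

To use an atlas-derived brain mesh instead of the surrogate, point a
scenario file's `mesh_kind: file` / `mesh_path:` at a tetrahedral `.msh`,
`.vtu` or `.xdmf` volume mesh in millimetres.

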