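# npbcmd — nonperiodic-boundary MD in a spherical cavity

Molecular-dynamics studies of solvated radicals and chromophores often
need a *finite* simulation geometry: a droplet of explicit solvent in a
sphere, embedded in a continuum, instead of a periodically replicated box.
`npbcmd` implements that setup end to end for method development and
desk-scale studies: a spherical-cavity MD engine with a quasi-analytical
conductor reaction field at the boundary, NVT and constant-pressure (NPT)
ensembles with a breathing cavity, adaptive optimization of the boundary
mean-field potential that keeps the solvent density flat up to the wall,
and a trajectory-mining pipeline (finite-sphere structural analysis,
validated medoid clustering, GRASP selection of representative frames for
downstream QM/MM work).

It is aimed at people building or dissecting boundary models — not at
production biomolecular MD.

## The model

A sphere Ω of radius *R* holds the system (nonperiodic boundary
conditions).  The environment outside contributes:

- **Reaction field** *U*<sub>RF</sub>: the conductor (C-PCM/COSMO) apparent
  surface charge σ on Γ = ∂Ω, which for a single sphere diagonalizes in
  spherical harmonics,

  σ<sub>lm</sub> = −f(ε) (2l+1) φ<sub>lm</sub> / (4π k<sub>e</sub> R),  E = R²/2 Σ σ<sub>lm</sub> φ<sub>lm</sub>,

  with φ<sub>lm</sub> the Lebedev-quadrature expansion of the solute
  potential on Γ.  Energies, atomic forces and dE/dV (for the barostat)
  come from one consistent discretization and reproduce the closed-form
  conductor (Kirkwood ε→∞) energy of an off-center charge,
  −k<sub>e</sub>q²R/2(R²−r²), to <10⁻⁴ relative at L<sub>max</sub> = 16.
- **Boundary mean field** *U*<sub>vdW</sub>(R − |r<sub>COM</sub>|): a radial
  polynomial that compensates the missing bulk attraction near the wall;
  it is optimized adaptively (constant-radius shells, density-feedback
  updates) and fitted by ridge regression with an evolutionary-strategy
  search of the shrinkage.
- **Rough wall**: stochastic thermal re-injection of any molecule whose
  center of mass leaves the sphere.

Dynamics: rotational velocity Verlet for rigid molecules (quaternion
midpoint iteration), RATTLE for constrained flexible ones, stochastic
velocity-rescaling thermostat, Clausius-virial pressure
P = (2E<sub>kin</sub> + Σ R<sub>AB</sub>·f<sub>AB</sub>)/3V − dE<sub>solv</sub>/dV and a
weak-coupling barostat that scales coordinates *and* the cavity radius.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

A unit charge halfway off-center in a 10 Å conductor-bounded cavity:

```python
import numpy as np
from npbcmd.sphere_grid import HarmonicBasis, build_lebedev_grid
from npbcmd.ddcosmo import ChargeDistribution, ReactionFieldSolver, SphericalCavity

solver = ReactionFieldSolver(HarmonicBasis(16), build_lebedev_grid(302))
cavity = SphericalCavity(center=np.zeros(3), radius=10.0)
ion = ChargeDistribution(charges=[1.0], positions=[[0.0, 0.0, 5.0]])
res = solver.compute(ion, cavity)
print(f"solvation energy: {res.energy:.4f} kJ/mol")
print(f"force on the ion: {res.forces[0].round(4)} kJ/mol/Å")
print(f"dE/dV:            {res.dE_dV:.6f} kJ/mol/Å³")
```

```
solvation energy: -92.6236 kJ/mol
force on the ion: [ 0.      0.     12.3498] kJ/mol/Å
dE/dV:            0.012285 kJ/mol/Å³
```

The energy matches the closed form −k<sub>e</sub>R/2(R²−r²) = −92.6236
kJ/mol; the force points outward (+z) because the induced surface charge
attracts the ion toward the nearer boundary; the positive dE/dV says
solvation weakens as the cavity grows, which is the term the barostat
feels.

A 10 ps thermostatted droplet — 86 SPC waters at the experimental density
in an 8.5 Å sphere with the reaction field on:

```python
from npbcmd.fixtures import BuildSpec, build_water_sphere
from npbcmd.dynamics import SimulationConfig, run_simulation

pos, topo = build_water_sphere(BuildSpec(model="SPC", radius=8.5, seed=1))
config = SimulationConfig(ensemble="NVT", dt=0.002, n_steps=5000,
                          radius=8.5, temperature=298.15, tau_t=0.4,
                          reaction_field=True, seed=2,
                          log_stride=500, traj_stride=500)
result = run_simulation(topo, pos.copy(), config)
print(result.log[["time", "T", "P", "E_pair", "E_reaction_field"]]
      .tail(3).round(2).to_string(index=False))
print("wall events:", result.wall_events)
```

```
 time      T       P   E_pair  E_reaction_field
  8.0 284.38 2569.35 -3065.08            -70.58
  9.0 297.56  685.83 -2976.18            -95.76
 10.0 327.78  468.07 -2976.55            -89.61
wall events: 377
```

Temperature fluctuates around the 298.15 K set-point (±15% swings are
normal for ~500 degrees of freedom), the instantaneous pressure of a small
droplet swings over thousands of bar, the pair energy ≈ −35 kJ/mol per
molecule is liquid-like, and the reaction field contributes ≈ −90 kJ/mol of
boundary stabilization.  `result.frames` holds the trajectory for the
analysis modules (`rdf_npbc`, `shell_density`, `f_hb`) and the
clustering/GRASP pipeline (`snapshot_selection`).

The same functionality is scriptable from the shell:

```sh
npbcmd build --model SPC --radius 8.5 --seed 1 --out-prefix water
npbcmd simulate --config run.yaml --coordinates water.xyz \
                --topology water.topology.yaml --out-prefix run
npbcmd analyze run.traj.xyz --topology water.topology.yaml --rdf O-O
npbcmd rf-energy ion.xyz --radius 10 --charge-column
npbcmd select-frames --features features.tsv --total 64 --seed 1
```

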