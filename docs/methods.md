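# Methods

`npbcmd` simulates a finite droplet of rigid molecular solvent inside a
spherical cavity — nonperiodic boundary conditions (NPBC) — and mines the
resulting trajectories.  This note documents the models, the numerical
choices, and what the desk-scale defaults do and do not demonstrate.

## The boundary model

A sphere Ω of radius *R* centered at the origin holds the system.  Three
terms represent the environment outside Ω:

**Conductor reaction field (single-sphere ddCOSMO).**  The solute/solvent
charges q_k at r_k generate a potential Φ on the boundary Γ; an apparent
surface charge σ on Γ cancels it (conductor limit; a scaled mode multiplies
the response by f(ε) = (ε−1)/ε).  For a single sphere the integral equation
is diagonal in spherical harmonics:

    Φ(R·ŝ) = Σ_lm φ_lm Y_lm(ŝ),    σ_lm = −f(ε) (2l+1) φ_lm / (4π k_e R),
    E = R²/2 · Σ_lm σ_lm φ_lm  ≤ 0.

φ_lm is obtained by Lebedev–Laikov quadrature of Φ over Γ; σ is represented
as point charges Q_n = 4π w_n R² σ(R s_n) at the quadrature nodes.  Energy,
atomic forces (q_k times the field of the Q_n) and the cavity-volume
derivative dE/dV (needed by the barostat) all use this one discretization,
so the analytic forces are the *exact* derivatives of the discrete energy —
central-difference checks agree to ≲1e−8 relative at fixed grid and L_max.
The truncation error is physical: against the closed-form conductor
(Kirkwood ε→∞) energy −k_e q²R/(2(R²−r²)) of an off-center charge, L_max = 16
with the 302-node grid is converged to <1e−4 relative for r/R ≤ 0.5.
Defaults for dynamics are L_max = 10 and the 302-node grid; these are
configuration, not convergence claims.

During dynamics the node charges are Gaussian-smeared with width equal to
the mean node spacing √(4π/N_g)·R (≈1.7 Å for 302 nodes at R = 8.5 Å),
using erf-screened interactions.  The exact point-node discretization is
singular when a hydrogen strays within a fraction of an ångström of a node,
which happens routinely for molecules pressed against the wall; resolving
the surface charge below the grid's own angular resolution is spurious
detail.  Smearing width is exposed as `EnergyModel(rf_smear=...)` in units
of the node spacing.  The narrow-smearing regime (≤0.4 spacings) lets the
truncated image-charge attraction glue molecules to the boundary and is not
recommended.

**Boundary mean field (U_vdW).**  A radial potential acting on molecular
centers of mass, a function of the boundary distance x = R − |r_COM| so it
translates rigidly with a breathing wall.  Two representations: a
polynomial Σ a_i x^i (zero beyond its activation range; Horner evaluation)
and a piecewise-linear table used while the potential is being optimized.
A degree-10 polynomial parameterization for TIP3P-FB water is packaged as a
constant (active for x ≤ 8 Å; it was calibrated on ≥15 Å spheres and spans
too much of a small droplet to be meaningful at R ≈ 8.5 Å).

**Rough wall.**  Whenever a molecule's COM crosses R outward, its COM
velocity is redirected uniformly at random (flipped inward if outward) with
magnitude set to the Maxwell mean speed √(8k_BT/πM), and its angular
momentum direction is resampled with magnitude chosen so the rotational
energy equals the equipartition mean (3/2)k_BT.  A molecule outside the
sphere but already moving inward is left alone: one reset per crossing.
Re-kicking on every step while the COM re-enters would repeat an energy
bias ~5× per crossing — wall-crossing molecules are flux-selected (mean
translational energy 2k_BT) but re-injected at the mean speed (≈1.27k_BT),
so each reset cools the droplet slightly.  With a rigid wall and no
confining mean field this bias is visible: the 86-molecule droplet runs
≈3–4% below the thermostat set-point.  A converged U_vdW suppresses wall
traffic and with it the bias; see Limitations.

## Dynamics

*Rigid bodies* (the default for water) propagate by rotational velocity
Verlet: translations by standard velocity Verlet on the COM; orientations
by a quaternion midpoint step whose time derivative q̇ = ½ q∘(0, ω_body) is
iterated to self-consistency (convergence 1e−9 by default, matching the
integrator it follows), with renormalization every step.  Reference
coordinates are stored in the principal frame of each body's inertia
tensor; linear bodies are not supported.  Torque-free tops conserve |L| and
rotational energy to ~1e−8 over 10⁴ steps and follow the Euler-equation
polhode of a high-accuracy ODE reference.

*Point-atom molecules* use velocity Verlet with RATTLE (iterative
position/velocity constraint sweeps, tolerance 1e−10).

*Thermostat*: stochastic velocity rescaling (canonical sampling through a
global rescale built from one Gaussian and one χ² variate), applied to
translational velocities and angular momenta alike.  Degrees of freedom:
3 per free atom minus constraints, 6 per (nonlinear) rigid body; frozen
solutes are excluded everywhere.

*Pressure and barostat*: the isotropic pressure is
P = (2E_kin + W)/(3V) − dE_solv/dV, with E_kin the molecular translational
(COM) kinetic energy and W the molecular virial Σ R_AB·f_ij accumulated
over atom pairs with COM separations — the origin-independent form
appropriate to rigid molecules (it also sidesteps constraint-force
virials).  The reaction field enters through −dE/dV rather than the pair
virial, avoiding double counting; a switch (`rf_in_pressure`) exists
because the two conventions differ only through the boundary term.  Weak
coupling rescales molecule COMs and R by μ = [1 − αβ(δt/τ_P)(P₀−P)]^{1/3}
each step (α = 1 for the sphere; μ clamped to [0.95, 1.05] as runaway
protection).  Rescaling COMs rather than atoms preserves rigid geometry.

The driver sequence per step: forces → integrate → rough wall → thermostat
→ (NPT) pressure + scaling.  Trajectories are XYZ frames whose comment line
carries `time=… radius=…`; a plain-text log records T, P, R and energy
terms.  Runs are bit-reproducible for a given seed on one platform.

## Mean-field optimization and fit

The adaptive loop divides the sphere into constant-width shells (80 by
default) and, after each cycle of MD, nudges each shell's tabulated energy
by δ·(ρ̄/ρ₀ − 1) (default gain 1 kJ/mol, capped at 0.3 kJ/mol per update):
overdense shells become more repulsive, underdense more attractive.  Two
desk-scale concessions: shells with too few molecules for a density
estimate (centers inside 3 Å) are pinned at zero, and the geometric
depletion layer within 0.8 Å of the wall — which a molecular COM cannot
populate — is excluded from the target and carries the last optimized value
instead, since "filling" it is impossible and the attempt produces a
runaway attractive boundary.

The converged table is truncated where |U| < 0.1 kJ/mol and fitted by
polynomials of degree 0–12: ridge regression on an abscissa scaled to
order one (solved in augmented least-squares form, which keeps the
conditioning of the design matrix rather than its square), the shrinkage λ
of each degree optimized in log-space by a (λ, μ)-comma evolutionary
strategy (100 children, 25 truncation-selected parents, crossover 0.5,
mutation rates 0.3/0.5, Gaussian mutation annealed ×0.99, 500 iterations by
default).  The EA objective is the held-out-half RMSE on the deterministic
alternating-index train/test split — the same learning-curve objective that
then selects the degree (lowest test RMSE, ties broken by the highest test
R², then the lowest degree), so the chosen λ is never worse than any fixed
λ on those curves.

## Trajectory analysis

*g(r) under NPBC*: central atoms restricted to a ball r_sel around the
center with r_sel + r_max ≤ R, so every neighbor shell lies inside the
cavity; ideal-gas normalization uses the frame's global number density.
*First-peak HWHM*: peak position refined parabolically; baseline = minimum
of g left of the peak; the half-height crossing is found on the *left*
(rising) flank with linear interpolation.  The left side is the steep
repulsive flank and remains well defined in small droplets where the
first/second-shell depletion zone (the right flank's reference) washes out.
*Shell densities*: equal-volume shells r_i = R(i/n)^{1/3}, molecules
assigned by COM, mass density in g/cm³, mean ± sd over frames.
*Hydrogen bonds*: a continuous strength per donor–acceptor pair,
S_r(r)·S_θ(θ) with logistic switches in the H···A distance (midpoint
2.5 Å, steepness 10 Å⁻¹) and the D–H···A angle (midpoint 140°, steepness
0.1 deg⁻¹), all configurable; each pair contributes in [0, 1].

## Snapshot selection

Features are the first and second smallest distances from chosen solute
sites to each solvent atom type.  PCA (centered, unscaled — all features
share units) keeps the smallest dimension exceeding 90% explained
variance.  PAM (BUILD + best-improvement SWAP, evaluated with the
nearest/second-nearest medoid bookkeeping so a sweep costs O(k·n²)) is run
for k = 2…20; the cluster count is the consensus of at least three of:
Silhouette (max), Dunn (max), Calinski–Harabasz (max) and the WSS elbow
(argmax of the discrete second difference).  Without a three-vote consensus
the most-voted (smallest on ties) k is returned with a flag.

Representatives are drawn per cluster with largest-remainder proportional
budgets, the medoid always included, by GRASP maximizing the
density-weighted total dissimilarity DS(F) = Σ_{i<j∈F} w_i w_j d(i,j) with
w_i ∝ (kNN density)^{−1/2} (k = 10, normalized to mean 1) so sparse fringes
are covered.  Construction samples uniformly from the restricted candidate
list — by default the top-α band of incremental contribution
[ΔDS_max − α(ΔDS_max − ΔDS_min), ΔDS_max], the standard maximization
convention; the literal low band is available behind
`GRASPConfig(literal_rcl=True)`.  Local search swaps each member against
its nearest neighbors (up to 5% of the set) until no improvement; the best
of 100 restarts is kept.  On instances small enough to enumerate, the
default configuration attains the brute-force optimum in ≥95% of random
instances.

## Synthetic data and builders

Water spheres are built at the experimental density (0.997 g/cm³ at
298.15 K → 86 molecules at R = 8.5 Å): molecule count N = round(ρV/m),
jittered-lattice placement clipped to R − 0.8 Å, random orientations, and
rigid-body steepest descent with capped moves until overlap-free
(intermolecular contacts > 1.5 Å).  Parameter sets: SPC and TIP3P-FB
(geometry, charges and LJ from the original ForceBalance parameterization;
its rigid-model dipole evaluates to 2.419 D).  A rigid toy nitroxide
fragment (C–N(–C)–O with two out-of-plane lone-pair sites) exercises the
solute/virtual-site machinery without any external topology.  Gaussian
mixtures with known labels stand in for MD feature spaces in clustering
tests; they reproduce cluster-size statistics but none of the time
correlation or manifold structure of real trajectories, so selection tests
validate the algorithms, not MD physics.

## Benchmarks and their scale

The bundled benchmarks (`npbcmd.benchmarks`, driven by
`scripts/acceptance.py`) use the 86-molecule, R = 8.5 Å droplet:

- NPT at a 1000 bar set-point (TIP3P-FB, dt = 2 fs, τ_T = 0.4 ps,
  τ_P = 4 ps, β = 4.5e−5 bar⁻¹, 120 ps with 20 ps discarded).  The sampled
  pressure mean lands within two block-averaged standard errors of the
  set-point.
- Paired NVT runs (SPC, 220 ps with 20 ps discarded) with a vacuum vs a
  conductor boundary; the first-peak O–O g(r) left HWHM quantifies
  overstructuring.  The expected direction is a broader peak (less
  structure) under the reaction field; at this droplet size, with the
  smeared surface charge and no converged boundary mean field, the
  measured contrast is small — of the order of the sampling noise of a
  few-hundred-picosecond run.

These are deliberately small systems and short trajectories chosen so the
whole suite runs in minutes on one core; production studies of boundary
artifacts use spheres up to R = 20 Å and nanosecond sampling.

## Known limitations

- Without a converged solvent-specific U_vdW the vacuum-boundary droplet
  over-densifies its core (~10%) and the rough wall's flux-selection bias
  cools it a few percent; both sharpen the first g(r) peak, so absolute
  HWHM values at R = 8.5 Å come out ~0.04–0.06 Å narrower than runs that
  include a converged boundary mean field.  Converging that potential
  (nanoseconds of adaptive MD) is outside the bundled benchmarks' budget;
  `optimize-meanfield` implements the procedure itself.
- Single sphere only; no molecular-shaped cavities, no Ewald/PME (systems
  are finite by construction), no flexible intramolecular force field
  beyond holonomic constraints, no linear rigid bodies.
- The O(N²) direct charge sums are adequate to a few thousand atoms; there
  is no fast multipole summation.
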