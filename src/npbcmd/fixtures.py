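"""Deterministic builders for test systems and synthetic data.

Everything is a pure function of (spec, seed): rigid three-site water
spheres at experimental density (SPC and TIP3P-FB parameter sets packaged
as constants), a rigid toy nitroxide fragment with lone-pair virtual sites
for solute/solvent pipelines, and Gaussian-mixture feature-space
trajectories with known labels for the clustering and selection stages.
"""

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import AVOGADRO_VOL
from .forcefield import (MeanFieldPotential, RigidBody, Topology, VirtualSite,
                         pair_energy_forces, project_virtual_sites)

__all__ = [
    "WaterModel", "SPC", "TIP3P_FB", "BuildSpec", "ToySolute",
    "tip3p_fb_meanfield", "water_dipole", "build_water_sphere",
    "build_toy_nitroxide", "insert_solute", "synth_feature_trajectory",
]


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site water parameter set (LJ on oxygen only)."""

    name: str
    r_oh: float          # Å
    theta: float         # deg
    q_o: float           # e
    q_h: float           # e
    sigma_o: float       # Å
    epsilon_o: float     # kJ/mol
    mass_o: float = 15.9994
    mass_h: float = 1.008

    @property
    def mass(self) -> float:
        return self.mass_o + 2 * self.mass_h

    def site_coords(self) -> np.ndarray:
        """O, H1, H2 coordinates with the COM at the origin, HOH bisector +z."""
        half = np.radians(self.theta / 2.0)
        o = np.zeros(3)
        h1 = self.r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
        h2 = self.r_oh * np.array([-np.sin(half), 0.0, np.cos(half)])
        coords = np.stack([o, h1, h2])
        masses = np.array([self.mass_o, self.mass_h, self.mass_h])
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        return coords - com


SPC = WaterModel("SPC", r_oh=1.0, theta=109.47, q_o=-0.82, q_h=0.41,
                 sigma_o=3.166, epsilon_o=0.650)

#: TIP3P-FB, parameters of the original ForceBalance parameterization.
TIP3P_FB = WaterModel("TIP3P-FB", r_oh=1.01181082494, theta=108.14844252,
                      q_o=-0.848448690103, q_h=0.424224345052,
                      sigma_o=3.17796456355, epsilon_o=0.652143528104)

WATER_MODELS = {"SPC": SPC, "TIP3P-FB": TIP3P_FB}

#: boundary mean-field polynomial for TIP3P-FB water, a_0..a_10 in
#: kJ/mol/Å^i of the boundary distance x = R - |r_COM|, active for x <= 8 Å.
TIP3P_FB_MEANFIELD_COEFFS = np.array([
    6.958446e+00, -1.381768e+01, -7.095241e+00, 2.678593e+01,
    -2.224122e+01, 9.410601e+00, -2.343013e+00, 3.571387e-01,
    -3.280733e-02, 1.669372e-03, -3.616741e-05,
])


def tip3p_fb_meanfield() -> MeanFieldPotential:
    """The packaged degree-10 boundary potential for TIP3P-FB water."""
    return MeanFieldPotential(TIP3P_FB_MEANFIELD_COEFFS.copy(), cutoff_start=8.0)


def water_dipole(model: WaterModel) -> float:
    """Dipole moment of the rigid model in Debye."""
    from .constants import DEBYE_PER_EA
    coords = model.site_coords()
    q = np.array([model.q_o, model.q_h, model.q_h])
    return float(np.linalg.norm((q[:, None] * coords).sum(0))) * DEBYE_PER_EA


@dataclass
class BuildSpec:
    """Recipe for a water sphere at a target mass density."""

    model: str = "SPC"
    radius: float = 8.5          # Å
    density: float = 0.997       # g/cm³ at 298.15 K
    seed: int = 0

    def __post_init__(self):
        if self.radius < 6.0:
            raise ValueError("cavity radius must be >= 6 Å")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.model not in WATER_MODELS:
            raise ValueError(f"unknown water model {self.model!r}")


def n_molecules_for(spec: BuildSpec) -> int:
    model = WATER_MODELS[spec.model]
    volume = 4.0 / 3.0 * np.pi * spec.radius**3
    return int(round(spec.density * AVOGADRO_VOL / model.mass * volume))


def water_topology(model: WaterModel, n_molecules: int,
                   mol_offset: int = 0) -> Topology:
    n = 3 * n_molecules
    rep = lambda o, h: np.tile([o, h, h], n_molecules)
    topo = Topology(
        masses=rep(model.mass_o, model.mass_h),
        charges=rep(model.q_o, model.q_h),
        lj_sigma=rep(model.sigma_o, 0.0),
        lj_epsilon=rep(model.epsilon_o, 0.0),
        molecule=np.repeat(np.arange(n_molecules) + mol_offset, 3),
        elements=["O", "H", "H"] * n_molecules,
        rigid_bodies=[RigidBody(atoms=np.arange(3 * i, 3 * i + 3))
                      for i in range(n_molecules)],
    )
    return topo


def build_water_sphere(spec: BuildSpec, relax_steps: int = 150):
    """Jittered-lattice water sphere, steepest-descent relaxed.

    Returns ``(positions, topology)``; deterministic for a given seed.
    """
    model = WATER_MODELS[spec.model]
    n_mol = n_molecules_for(spec)
    rng = np.random.default_rng(spec.seed)
    margin = 0.8
    r_place = spec.radius - margin
    a = (4.0 / 3.0 * np.pi * r_place**3 / n_mol) ** (1.0 / 3.0)
    for _ in range(100):
        k = int(np.ceil(r_place / a)) + 1
        grid = np.arange(-k, k + 1) * a
        pts = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"),
                       axis=-1).reshape(-1, 3)
        pts = pts[np.linalg.norm(pts, axis=1) <= r_place]
        if len(pts) >= n_mol:
            break
        a *= 0.98
    else:  # pragma: no cover
        raise RuntimeError("could not place the requested number of molecules")
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    coms = pts[order[:n_mol]] + rng.uniform(-0.1 * a, 0.1 * a, size=(n_mol, 3))

    from .dynamics import quat_to_matrix, random_quaternions
    quats = random_quaternions(n_mol, rng)
    A = quat_to_matrix(quats)
    template = model.site_coords()
    positions = (coms[:, None, :]
                 + np.einsum("nij,kj->nki", A, template)).reshape(-1, 3)
    topo = water_topology(model, n_mol)
    topo.initialize_bodies(positions)
    positions = _steepest_descent(positions, topo, coms, quats, template,
                                  r_place, relax_steps)
    min_d = _kernels.min_intermolecular_distance(positions, topo.molecule)
    if min_d <= 1.5:
        raise RuntimeError(
            f"builder could not reach an overlap-free packing (min distance "
            f"{min_d:.2f} Å); the requested density may be unreachable")
    return positions, topo


def _steepest_descent(positions, topo, coms, quats, template, r_max, n_steps,
                      max_disp=0.1, max_rot=0.05):
    """Rigid-body steepest descent on the pair energy (capped moves)."""
    from .dynamics import quat_mul, quat_to_matrix

    n_mol = len(coms)
    masses = topo.masses.reshape(n_mol, 3)
    e_prev, _, _ = pair_energy_forces(positions, topo)
    step = max_disp
    for _ in range(n_steps):
        _, forces, _ = pair_energy_forces(positions, topo)
        f = forces.reshape(n_mol, 3, 3)
        pos3 = positions.reshape(n_mol, 3, 3)
        f_com = f.sum(axis=1)
        rel = pos3 - coms[:, None, :]
        torque = np.cross(rel, f).sum(axis=1)
        fn = np.linalg.norm(f_com, axis=1, keepdims=True)
        tn = np.linalg.norm(torque, axis=1, keepdims=True)
        d_com = f_com / np.maximum(fn, 1e-12) * np.minimum(step, 0.002 * fn)
        new_coms = coms + d_com
        rad = np.linalg.norm(new_coms, axis=1, keepdims=True)
        new_coms = np.where(rad > r_max, new_coms * (r_max / rad), new_coms)
        angle = np.minimum(max_rot, 0.001 * tn)
        axis = torque / np.maximum(tn, 1e-12)
        half = 0.5 * angle
        dq = np.concatenate([np.cos(half), axis * np.sin(half)], axis=1)
        new_quats = quat_mul(dq, quats)
        new_quats /= np.linalg.norm(new_quats, axis=1, keepdims=True)
        A = quat_to_matrix(new_quats)
        new_positions = (new_coms[:, None, :]
                         + np.einsum("nij,kj->nki", A, template)).reshape(-1, 3)
        e_new, _, _ = pair_energy_forces(new_positions, topo)
        if e_new < e_prev:
            coms, quats, positions, e_prev = new_coms, new_quats, new_positions, e_new
            step = min(step * 1.1, max_disp)
        else:
            step *= 0.5
            if step < 1e-4:
                break
    return positions


# ---------------------------------------------------------------------------
# toy solute

@dataclass
class ToySolute:
    """A rigid fragment to be frozen at the cavity center."""

    positions: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    elements: list
    virtual_sites: list          # VirtualSite with fragment-local indices


def build_toy_nitroxide() -> ToySolute:
    """A 4-atom nitroxide mimic (C-N(-C)-O) plus two lone-pair sites.

    The lone pairs are massless charge sites placed symmetrically above and
    below the C-N-O plane by the out-of-plane construction, standing in for
    the nitroxide-oxygen lone pairs of a full spin-label topology.
    """
    positions = np.array([
        [1.33, 0.0, -0.47],    # C1
        [0.0, 0.0, 0.0],       # N
        [-1.33, 0.0, -0.47],   # C2
        [0.0, 0.0, 1.28],      # O
        [0.0, 0.0, 0.0],       # LP1 (projected)
        [0.0, 0.0, 0.0],       # LP2 (projected)
    ])
    sites = [
        VirtualSite(site=4, parents=(3, 1, 0), a=-0.15, b=0.0, c=0.12),
        VirtualSite(site=5, parents=(3, 1, 0), a=-0.15, b=0.0, c=-0.12),
    ]
    solute = ToySolute(
        positions=positions,
        masses=np.array([12.011, 14.007, 12.011, 15.999, 0.0, 0.0]),
        charges=np.array([0.15, 0.15, 0.15, 0.25, -0.35, -0.35]),
        lj_sigma=np.array([3.40, 3.25, 3.40, 2.96, 0.0, 0.0]),
        lj_epsilon=np.array([0.36, 0.71, 0.36, 0.88, 0.0, 0.0]),
        elements=["C", "N", "C", "O", "X", "X"],
        virtual_sites=sites,
    )
    return solute


def insert_solute(positions: np.ndarray, topo: Topology, solute: ToySolute,
                  radius: float = None):
    """Center the solute and delete solvent molecules within vdW contact.

    Contact distance of an (i, j) pair is the Lorentz mixing (σ_i+σ_j)/2;
    atoms without LJ parameters (σ = 0) never trigger a removal.  Returns
    ``(positions, topology, n_removed)`` with the solute first (molecule 0)
    and all solute atoms frozen.
    """
    ns = len(solute.masses)
    if radius is not None:
        extent = np.linalg.norm(solute.positions, axis=1).max()
        if extent >= radius:
            raise ValueError("solute does not fit inside the cavity")
    sol_pos = solute.positions.copy()
    keep_mols = []
    n_mol = topo.n_molecules
    for mol in range(n_mol):
        sel = topo.molecule == mol
        d = np.linalg.norm(positions[sel][:, None, :] - sol_pos[None, :, :],
                           axis=2)
        contact = 0.5 * (topo.lj_sigma[sel][:, None] + solute.lj_sigma[None, :])
        contact[(topo.lj_sigma[sel][:, None] == 0)
                | (solute.lj_sigma[None, :] == 0)] = 0.0
        if np.all(d >= contact):
            keep_mols.append(mol)
    n_removed = n_mol - len(keep_mols)
    keep_atoms = np.isin(topo.molecule, keep_mols)
    old_bodies = [b for b in topo.rigid_bodies
                  if keep_atoms[np.asarray(b.atoms, int)].all()]
    index_map = -np.ones(topo.n_atoms, dtype=int)
    index_map[keep_atoms] = ns + np.arange(int(keep_atoms.sum()))
    mol_map = {m: i + 1 for i, m in enumerate(keep_mols)}

    new_positions = np.vstack([sol_pos, positions[keep_atoms]])
    new_topo = Topology(
        masses=np.concatenate([solute.masses, topo.masses[keep_atoms]]),
        charges=np.concatenate([solute.charges, topo.charges[keep_atoms]]),
        lj_sigma=np.concatenate([solute.lj_sigma, topo.lj_sigma[keep_atoms]]),
        lj_epsilon=np.concatenate([solute.lj_epsilon,
                                   topo.lj_epsilon[keep_atoms]]),
        molecule=np.concatenate([
            np.zeros(ns, dtype=int),
            [mol_map[m] for m in topo.molecule[keep_atoms]]]),
        elements=list(solute.elements)
        + [e for e, k in zip(topo.elements, keep_atoms) if k],
        rigid_bodies=[RigidBody(atoms=index_map[np.asarray(b.atoms, int)])
                      for b in old_bodies],
        virtual_sites=[VirtualSite(site=vs.site, parents=vs.parents,
                                   a=vs.a, b=vs.b, c=vs.c)
                       for vs in solute.virtual_sites],
        frozen=np.concatenate([np.ones(ns, dtype=bool),
                               np.zeros(int(keep_atoms.sum()), dtype=bool)]),
    )
    project_virtual_sites(new_positions, new_topo)
    return new_positions, new_topo, n_removed


# ---------------------------------------------------------------------------
# synthetic feature-space trajectories

def synth_feature_trajectory(mixture, n_frames: int, seed: int,
                             stride_ps: float = 10.0):
    """Gaussian-mixture samples with known labels.

    ``mixture`` is a list of (weight, mean, cov) with cov a scalar, vector
    or full matrix.  Returns (FeatureMatrix, labels).
    """
    from .snapshot_selection import FeatureMatrix

    weights = np.array([w for w, _, _ in mixture], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mixture weights must be non-negative, not all zero")
    weights = weights / weights.sum()
    means = [np.atleast_1d(np.asarray(m, float)) for _, m, _ in mixture]
    dim = len(means[0])
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(weights), size=n_frames, p=weights)
    values = np.empty((n_frames, dim))
    for c, (_, mean, cov) in enumerate(mixture):
        sel = labels == c
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = np.eye(dim) * cov
        elif cov.ndim == 1:
            cov = np.diag(cov)
        values[sel] = rng.multivariate_normal(means[c], cov,
                                              size=int(sel.sum()),
                                              method="svd") \
            if np.any(cov) else means[c]
    fm = FeatureMatrix(
        values=values,
        frame_indices=np.arange(n_frames),
        feature_names=[f"f{i}" for i in range(dim)],
        stride_ps=stride_ps,
    )
    return fm, labels
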