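"""Classical interactions for finite spherical (nonperiodic) systems.

Covers the Lennard-Jones + Coulomb pair sum (all pairs, no cutoff — the
system is finite), out-of-plane virtual sites, the radial boundary
mean-field potential that keeps the solvent density flat up to the wall,
and the stochastic "rough wall" re-injection of escaping molecules.
"""

from dataclasses import dataclass, field as dfield

import numpy as np

from . import _kernels
from .constants import ACC_UNIT, KB, KE_COULOMB, KE_UNIT, maxwell_mean_speed

__all__ = [
    "RigidBody",
    "VirtualSite",
    "Topology",
    "MeanFieldPotential",
    "pair_energy_forces",
    "project_virtual_sites",
    "spread_virtual_site_forces",
    "meanfield_energy_forces",
    "rough_wall",
]


@dataclass
class RigidBody:
    """Atoms moved as one rigid unit; geometry frozen at its reference shape.

    ``body_coords`` are reference coordinates in the principal frame of the
    inertia tensor, ``inertia`` the principal moments (amu·Å²).
    """

    atoms: np.ndarray
    body_coords: np.ndarray = None
    inertia: np.ndarray = None
    mass: float = 0.0

    def initialize(self, positions: np.ndarray, masses: np.ndarray) -> None:
        atoms = np.asarray(self.atoms, dtype=int)
        self.atoms = atoms
        m = masses[atoms]
        self.mass = float(m.sum())
        com = (m[:, None] * positions[atoms]).sum(axis=0) / self.mass
        rel = positions[atoms] - com
        # inertia tensor and principal frame
        inert = np.zeros((3, 3))
        for mi, ri in zip(m, rel):
            inert += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
        moments, axes = np.linalg.eigh(inert)
        if np.any(moments < 1e-8):
            raise ValueError("linear/degenerate rigid bodies are not supported")
        # right-handed principal frame
        if np.linalg.det(axes) < 0:
            axes[:, 2] *= -1
        self.inertia = moments
        self.body_coords = rel @ axes  # coordinates in principal frame


@dataclass
class VirtualSite:
    """Massless interaction site built from three parent atoms.

    Out-of-plane construction (u = p1-p0, v = p2-p0):
        x_site = x_p0 + a·u + b·v + c·(u × v)
    """

    site: int
    parents: tuple
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0


@dataclass
class Topology:
    """Per-atom parameters plus rigid-body/virtual-site/constraint structure.

    Nonbonded exclusions are molecular: every intramolecular pair is
    excluded from the LJ/Coulomb sum (rigid or constrained molecules have
    no meaningful intramolecular nonbonded terms here).
    """

    masses: np.ndarray
    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    molecule: np.ndarray
    elements: list = dfield(default_factory=list)
    rigid_bodies: list = dfield(default_factory=list)
    virtual_sites: list = dfield(default_factory=list)
    constraints: list = dfield(default_factory=list)  # (i, j, distance)
    frozen: np.ndarray = None

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.molecule = np.asarray(self.molecule, dtype=np.int64)
        if self.frozen is None:
            self.frozen = np.zeros(self.n_atoms, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        for i, j, d in self.constraints:
            if d <= 0:
                raise ValueError("constraint distances must be positive")
        for vs in self.virtual_sites:
            if self.masses[vs.site] != 0.0:
                raise ValueError("virtual sites must be massless")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule.max()) + 1 if self.n_atoms else 0

    def initialize_bodies(self, positions: np.ndarray) -> None:
        for body in self.rigid_bodies:
            body.initialize(positions, self.masses)

    def molecule_com(self, positions: np.ndarray):
        """Mass-weighted molecule centers; returns (com (M,3), mol mass (M,))."""
        nm = self.n_molecules
        w = self.masses
        mmass = np.bincount(self.molecule, weights=w, minlength=nm)
        com = np.empty((nm, 3))
        for ax in range(3):
            com[:, ax] = np.bincount(
                self.molecule, weights=w * positions[:, ax], minlength=nm) / mmass
        return com, mmass


# ---------------------------------------------------------------------------
# pairwise interactions

def pair_energy_forces(positions: np.ndarray, topo: Topology):
    """All-pairs LJ + Coulomb with intramolecular exclusion.

    Returns ``(energy, forces, virial)`` where the virial is the
    origin-independent molecular form Σ R_AB·f_ij (COM separations),
    the one entering the pressure of a rigid molecular fluid.
    """
    com, _ = topo.molecule_com(positions)
    forces_out = np.zeros_like(positions)
    e_lj, e_c, w, n_overlap = _kernels.pair_kernel(
        positions, topo.charges, topo.lj_sigma, topo.lj_epsilon,
        topo.molecule, com, KE_COULOMB, forces_out)
    if n_overlap:
        raise ValueError(f"{n_overlap} atom pair(s) closer than 1e-6 Å")
    return e_lj + e_c, forces_out, w


# ---------------------------------------------------------------------------
# virtual sites

def project_virtual_sites(positions: np.ndarray, topo: Topology) -> np.ndarray:
    """Place every virtual site from its parents (idempotent)."""
    for vs in topo.virtual_sites:
        p0, p1, p2 = (positions[p] for p in vs.parents)
        u = p1 - p0
        v = p2 - p0
        w = np.cross(u, v)
        if vs.c != 0.0 and np.linalg.norm(w) < 1e-10 * max(
                np.linalg.norm(u) * np.linalg.norm(v), 1e-30):
            raise ValueError(
                f"degenerate (collinear) parents for out-of-plane site {vs.site}")
        positions[vs.site] = p0 + vs.a * u + vs.b * v + vs.c * w
    return positions


def spread_virtual_site_forces(positions: np.ndarray, forces: np.ndarray,
                               topo: Topology) -> np.ndarray:
    """Transfer site forces onto parents by the chain rule; zero site force."""
    for vs in topo.virtual_sites:
        p0, p1, p2 = vs.parents
        u = positions[p1] - positions[p0]
        v = positions[p2] - positions[p0]
        f = forces[vs.site]
        # gradients of x_site w.r.t. parents, transposed action on f
        f1 = vs.a * f + vs.c * np.cross(v, f)
        f2 = vs.b * f - vs.c * np.cross(u, f)
        forces[p1] += f1
        forces[p2] += f2
        forces[p0] += f - f1 - f2
        forces[vs.site] = 0.0
    return forces


# ---------------------------------------------------------------------------
# boundary mean-field potential

@dataclass
class MeanFieldPotential:
    """Radial polynomial acting on molecule COMs near the boundary.

    The argument is the distance from the boundary, x = R - |r_COM|, so the
    potential translates rigidly with a breathing wall.  It is identically
    zero for x > ``cutoff_start`` and evaluates Σ a_i x^i inside.
    """

    coefficients: np.ndarray
    cutoff_start: float
    anchor: str = "boundary"

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) - 1 > 12:
            raise ValueError("polynomial degree must be <= 12")

    def __call__(self, x):
        """Horner evaluation of the polynomial (0 beyond cutoff_start)."""
        x = np.asarray(x, dtype=float)
        acc = np.zeros_like(x)
        for a in self.coefficients[::-1]:
            acc = acc * x + a
        return np.where(x <= self.cutoff_start, acc, 0.0)

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        acc = np.zeros_like(x)
        for i in range(len(c) - 1, 0, -1):
            acc = acc * x + i * c[i]
        return np.where(x <= self.cutoff_start, acc, 0.0)


def meanfield_energy_forces(positions: np.ndarray, topo: Topology,
                            potential: MeanFieldPotential, radius: float,
                            center=None):
    """Boundary mean-field energy/forces on molecule COMs.

    Forces act along the radial unit vector and are distributed to the
    molecule's atoms by mass fraction.  COMs beyond the wall are clamped to
    boundary distance 0 (the rough wall takes over there).
    Returns ``(energy, forces, virial)``.
    """
    center = np.zeros(3) if center is None else np.asarray(center, float)
    com, mmass = topo.molecule_com(positions)
    rel = com - center
    r = np.linalg.norm(rel, axis=1)
    x = np.clip(radius - r, 0.0, None)
    active = x <= potential.cutoff_start
    energy = float(potential(x[active]).sum())
    dU = potential.derivative(x)
    forces = np.zeros_like(positions)
    virial = 0.0
    f_active = np.flatnonzero(active & (r > 1e-12))
    if len(f_active):
        rhat = rel[f_active] / r[f_active, None]
        f_com = dU[f_active, None] * rhat      # dU/d|r| = -U'(x) -> F = +U'(x) r̂
        virial = float(np.einsum("ij,ij->", rel[f_active], f_com))
        mfrac = topo.masses / mmass[topo.molecule]
        for mol, fc in zip(f_active, f_com):
            sel = topo.molecule == mol
            forces[sel] = mfrac[sel, None] * fc[None, :]
    return energy, forces, virial


# ---------------------------------------------------------------------------
# rough wall

def rough_wall(state, topo: Topology, radius: float, temperature: float, rng):
    """Thermal re-injection of molecules whose COM left the sphere.

    The COM velocity direction is resampled uniformly on the unit sphere
    (flipped inward if pointing outward) with magnitude √(8k_BT/πM); for
    rigid bodies the angular momentum direction is resampled the same way
    with magnitude set so the rotational energy equals its equipartition
    mean (3/2)k_BT.  A molecule still outside the sphere but already
    moving inward is left alone — one reset per wall crossing, so repeat
    kicks do not systematically cool the droplet.  Returns the number of
    wall events.
    """
    from .dynamics import quat_to_matrix  # local import to avoid a cycle

    events = 0
    # rigid bodies: vectorized violation check, loop only over offenders
    if len(state.body_com):
        outside = np.flatnonzero(
            np.einsum("ij,ij->i", state.body_com, state.body_com)
            > radius * radius)
    else:
        outside = ()
    for ib in outside:
        body = topo.rigid_bodies[ib]
        if topo.frozen[body.atoms].any():
            continue
        com = state.body_com[ib]
        if np.dot(state.body_vcom[ib], com) < 0.0:
            continue  # already re-entering
        events += 1
        u = _random_unit(rng)
        if np.dot(u, com) > 0:
            u = -u
        state.body_vcom[ib] = u * maxwell_mean_speed(temperature, body.mass)
        ldir = _random_unit(rng)
        A = quat_to_matrix(state.body_quat[ib][None, :])[0]
        ldir_body = A.T @ ldir
        denom = float(np.sum(ldir_body**2 / body.inertia))
        lmag = np.sqrt(3.0 * KB * temperature / (KE_UNIT * denom))
        state.body_angmom[ib] = lmag * ldir
    # flexible / free molecules
    free_mols = _free_molecules(topo)
    if len(free_mols):
        com, mmass = topo.molecule_com(state.positions)
        for mol in free_mols:
            c = com[mol]
            if np.linalg.norm(c) <= radius:
                continue
            sel = (topo.molecule == mol) & (topo.masses > 0)
            m = topo.masses[sel]
            vcom = (m[:, None] * state.velocities[sel]).sum(axis=0) / m.sum()
            if np.dot(vcom, c) < 0.0:
                continue  # already re-entering
            events += 1
            u = _random_unit(rng)
            if np.dot(u, c) > 0:
                u = -u
            vnew = u * maxwell_mean_speed(temperature, float(m.sum()))
            state.velocities[sel] += vnew - vcom
    return events


def _free_molecules(topo: Topology):
    if not hasattr(topo, "_free_mol_cache"):
        in_body = np.zeros(topo.n_atoms, dtype=bool)
        for body in topo.rigid_bodies:
            in_body[body.atoms] = True
        sel = ~in_body & ~topo.frozen & (topo.masses > 0)
        topo._free_mol_cache = np.unique(topo.molecule[sel]) \
            if topo.n_atoms else np.zeros(0, dtype=int)
    return topo._free_mol_cache


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n
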