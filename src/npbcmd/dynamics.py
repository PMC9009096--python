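"""Time propagation in the spherical cavity.

Velocity Verlet with RATTLE for point-atom molecules, a rotational
velocity-Verlet scheme (self-consistent quaternion midpoint iteration) for
rigid bodies, the stochastic velocity-rescaling (canonical sampling)
thermostat, Clausius-virial pressure, and the weak-coupling barostat with a
breathing cavity radius.

The cavity center is the coordinate origin throughout the engine.
"""

from dataclasses import dataclass, field as dfield
import math

import numpy as np

from .constants import ACC_UNIT, KB, KE_UNIT, PRESSURE_UNIT
from .forcefield import (MeanFieldPotential, Topology, meanfield_energy_forces,
                         pair_energy_forces, project_virtual_sites,
                         rough_wall, spread_virtual_site_forces)

__all__ = [
    "SystemState", "ThermostatParams", "BarostatParams", "SimulationConfig",
    "quat_to_matrix", "quat_mul",
    "rattle_project", "velocity_verlet_step", "rigid_body_step",
    "bussi_scale_factor", "bussi_thermostat", "pressure", "berendsen_scale",
    "EnergyModel", "Simulation", "SimulationResult", "run_simulation",
    "maxwell_velocities",
]


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention; A(q) maps body -> space)

def quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    w2, x2, y2, z2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    A = np.empty(q.shape[:-1] + (3, 3))
    A[..., 0, 0] = 1 - 2 * (y * y + z * z)
    A[..., 0, 1] = 2 * (x * y - w * z)
    A[..., 0, 2] = 2 * (x * z + w * y)
    A[..., 1, 0] = 2 * (x * y + w * z)
    A[..., 1, 1] = 1 - 2 * (x * x + z * z)
    A[..., 1, 2] = 2 * (y * z - w * x)
    A[..., 2, 0] = 2 * (x * z - w * y)
    A[..., 2, 1] = 2 * (y * z + w * x)
    A[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return A


def random_quaternions(n: int, rng) -> np.ndarray:
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# state and parameter containers

@dataclass
class SystemState:
    """Positions/velocities plus rigid-body coordinates and the cavity radius."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    radius: float
    body_com: np.ndarray = None
    body_vcom: np.ndarray = None
    body_quat: np.ndarray = None
    body_angmom: np.ndarray = None
    rng: np.random.Generator = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")
        n_body = 0 if self.body_com is None else len(self.body_com)
        if n_body == 0:
            self.body_com = np.zeros((0, 3))
            self.body_vcom = np.zeros((0, 3))
            self.body_quat = np.zeros((0, 4))
            self.body_angmom = np.zeros((0, 3))

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time, positions=self.positions.copy(),
            velocities=self.velocities.copy(), radius=self.radius,
            body_com=self.body_com.copy(), body_vcom=self.body_vcom.copy(),
            body_quat=self.body_quat.copy(),
            body_angmom=self.body_angmom.copy(), rng=self.rng)


@dataclass
class ThermostatParams:
    temperature: float
    tau: float = 0.4

    def __post_init__(self):
        if self.temperature <= 0 or self.tau <= 0:
            raise ValueError("temperature and coupling time must be positive")


@dataclass
class BarostatParams:
    pressure: float               # bar
    tau: float = 4.0              # ps
    compressibility: float = 4.5e-5   # bar⁻¹, liquid water
    alpha: float = 1.0            # box-type factor (1 for the sphere)

    def __post_init__(self):
        if self.compressibility <= 0 or self.tau <= 0:
            raise ValueError("tau and compressibility must be positive")


# ---------------------------------------------------------------------------
# RATTLE

def rattle_project(positions, velocities, constraints, masses, tol=1e-10,
                   max_iter=500, molecule_id=None):
    """Project positions onto |r_ij| = d_ij and velocities onto r_ij·v_ij = 0.

    Iterative Lagrange-multiplier sweeps (SHAKE-style with current bond
    directions); mass-weighted corrections conserve linear momentum.
    """
    pos = positions
    vel = velocities
    for it in range(max_iter):
        worst = 0.0
        for i, j, d in constraints:
            rij = pos[i] - pos[j]
            r2 = float(rij @ rij)
            diff = (r2 - d * d) / (d * d)
            worst = max(worst, abs(diff))
            if abs(diff) > tol:
                inv = 1.0 / masses[i] + 1.0 / masses[j]
                g = (r2 - d * d) / (2.0 * r2 * inv)
                pos[i] -= g * rij / masses[i]
                pos[j] += g * rij / masses[j]
        if worst <= tol:
            break
    else:
        where = f" (molecule {molecule_id})" if molecule_id is not None else ""
        raise RuntimeError(f"RATTLE position iteration did not converge{where}")
    for it in range(max_iter):
        worst = 0.0
        for i, j, d in constraints:
            rij = pos[i] - pos[j]
            vij = vel[i] - vel[j]
            dot = float(rij @ vij)
            scale = abs(dot) / (d * d)
            worst = max(worst, scale)
            if scale > tol:
                inv = 1.0 / masses[i] + 1.0 / masses[j]
                k = dot / (float(rij @ rij) * inv)
                vel[i] -= k * rij / masses[i]
                vel[j] += k * rij / masses[j]
        if worst <= tol:
            break
    else:
        where = f" (molecule {molecule_id})" if molecule_id is not None else ""
        raise RuntimeError(f"RATTLE velocity iteration did not converge{where}")
    return pos, vel


# ---------------------------------------------------------------------------
# rigid-body bookkeeping (vectorized over groups of equal-size bodies)

class RigidBodyEngine:
    def __init__(self, topo: Topology):
        self.topo = topo
        self.n_bodies = len(topo.rigid_bodies)
        self.groups = []
        if self.n_bodies:
            sizes = {}
            for ib, body in enumerate(topo.rigid_bodies):
                sizes.setdefault(len(body.atoms), []).append(ib)
            for size, idx in sizes.items():
                idx = np.asarray(idx)
                atoms = np.stack([topo.rigid_bodies[i].atoms for i in idx])
                coords = np.stack([topo.rigid_bodies[i].body_coords for i in idx])
                self.groups.append((idx, atoms, coords))
            self.mass = np.array([b.mass for b in topo.rigid_bodies])
            self.inertia = np.stack([b.inertia for b in topo.rigid_bodies])
            self.frozen = np.array([topo.frozen[b.atoms].any()
                                    for b in topo.rigid_bodies])
        else:
            self.mass = np.zeros(0)
            self.inertia = np.zeros((0, 3))
            self.frozen = np.zeros(0, dtype=bool)
        in_body = np.zeros(topo.n_atoms, dtype=bool)
        for body in topo.rigid_bodies:
            in_body[body.atoms] = True
        vsite = np.zeros(topo.n_atoms, dtype=bool)
        for vs in topo.virtual_sites:
            vsite[vs.site] = True
        self.free_atoms = np.flatnonzero(~in_body & ~vsite & (topo.masses > 0)
                                         & ~topo.frozen)

    def rebuild_positions(self, state: SystemState) -> None:
        A = quat_to_matrix(state.body_quat)
        for idx, atoms, coords in self.groups:
            rotated = np.einsum("nij,nkj->nki", A[idx], coords)
            state.positions[atoms] = state.body_com[idx][:, None, :] + rotated

    def com_force_torque(self, positions, forces):
        f_com = np.zeros((self.n_bodies, 3))
        torque = np.zeros((self.n_bodies, 3))
        for idx, atoms, _ in self.groups:
            f = forces[atoms]
            f_com[idx] = f.sum(axis=1)
            com = (self.topo.masses[atoms, None] * positions[atoms]).sum(axis=1) \
                / self.mass[idx, None]
            rel = positions[atoms] - com[:, None, :]
            torque[idx] = np.cross(rel, f).sum(axis=1)
        return f_com, torque

    def rotational_energy(self, state) -> float:
        if self.n_bodies == 0:
            return 0.0
        A = quat_to_matrix(state.body_quat)
        l_body = np.einsum("nji,nj->ni", A, state.body_angmom)
        live = ~self.frozen
        return 0.5 * KE_UNIT * float(np.sum(l_body[live]**2 / self.inertia[live]))


# ---------------------------------------------------------------------------
# energy model: pair + mean field + reaction field

class EnergyModel:
    """Bundles all position-dependent interactions for the driver.

    ``evaluate(positions, radius)`` returns (energies dict, forces, molecular
    virial, reaction-field dE/dV).
    """

    def __init__(self, topo: Topology, meanfield: MeanFieldPotential = None,
                 rf_solver=None, rf_smear: float = 1.0,
                 rf_factor: float = 1.0):
        self.topo = topo
        self.meanfield = meanfield
        self.rf = rf_solver
        # Gaussian smearing of the node charges, in units of the mean
        # node spacing √(4π/N_g)·R; regularizes close solvent-node
        # encounters at the boundary during dynamics
        self.rf_smear = rf_smear
        self.rf_factor = rf_factor
        self._charged = np.flatnonzero(topo.charges != 0.0)

    def evaluate(self, positions, radius):
        from .constants import KE_COULOMB
        from . import _kernels
        topo = self.topo
        project_virtual_sites(positions, topo)
        energies = {}
        e_pair, forces, virial = pair_energy_forces(positions, topo)
        energies["pair"] = e_pair
        if self.meanfield is not None:
            e_mf, f_mf, w_mf = meanfield_energy_forces(
                positions, topo, self.meanfield, radius)
            energies["meanfield"] = e_mf
            forces += f_mf
            virial += w_mf
        dEdV = 0.0
        if self.rf is not None:
            ch = self._charged
            nodes = radius * self.rf.grid.points
            qs = topo.charges[ch]
            ps = positions[ch]
            width = self.rf_smear * np.sqrt(4.0 * np.pi / self.rf.grid.size) \
                * radius
            phi_nodes = KE_COULOMB * _kernels.potential_at_points_smeared(
                nodes, ps, qs, width)
            phi_lm = self.rf.Yw.T @ phi_nodes
            l = self.rf.basis.l_of()
            sigma_lm = -self.rf_factor * (2.0 * l + 1.0) * phi_lm \
                / (4.0 * np.pi * KE_COULOMB * radius)
            Q = 4.0 * np.pi * self.rf.grid.weights * radius**2 * (self.rf.Y @ sigma_lm)
            e_rf = 0.5 * float(Q @ phi_nodes)
            energies["reaction_field"] = e_rf
            atom_field = np.zeros_like(ps)
            radial = _kernels.rf_pair_kernel(
                nodes, self.rf.grid.points, Q, ps, qs, width, atom_field)
            forces[ch] += qs[:, None] * (KE_COULOMB * atom_field)
            dEdV = (e_rf / radius - KE_COULOMB * radial) \
                / (4.0 * np.pi * radius**2)
        spread_virtual_site_forces(positions, forces, topo)
        forces[topo.frozen] = 0.0
        return energies, forces, virial, dEdV


# ---------------------------------------------------------------------------
# integrators

def velocity_verlet_step(state: SystemState, topo: Topology, force_fn, dt,
                         forces=None, tol=1e-10):
    """Standard velocity Verlet for point atoms with RATTLE constraints.

    ``force_fn(positions, radius)`` -> (energies, forces, virial, dEdV).
    Returns the force tuple at t+dt.  Frozen atoms do not move.
    """
    move = (topo.masses > 0) & ~topo.frozen
    if forces is None:
        forces = force_fn(state.positions, state.radius)
    f = forces[1]
    inv_m = np.zeros_like(topo.masses)
    inv_m[move] = 1.0 / topo.masses[move]
    state.velocities += 0.5 * dt * ACC_UNIT * f * inv_m[:, None]
    state.velocities[~move] = 0.0
    state.positions += dt * state.velocities
    _apply_rattle(state, topo, tol)
    out = force_fn(state.positions, state.radius)
    state.velocities += 0.5 * dt * ACC_UNIT * out[1] * inv_m[:, None]
    state.velocities[~move] = 0.0
    _apply_rattle_velocities(state, topo, tol)
    state.time += dt
    return out


def _constraints_by_molecule(topo: Topology):
    groups = {}
    for i, j, d in topo.constraints:
        mol = int(topo.molecule[i])
        groups.setdefault(mol, []).append((int(i), int(j), float(d)))
    return groups


def _apply_rattle(state, topo, tol):
    for mol, cons in _constraints_by_molecule(topo).items():
        rattle_project(state.positions, state.velocities, cons, topo.masses,
                       tol=tol, molecule_id=mol)


def _apply_rattle_velocities(state, topo, tol):
    # position sweep is a no-op when constraints already hold
    _apply_rattle(state, topo, tol)


def rigid_body_step(state: SystemState, topo: Topology, force_fn, dt,
                    eps=1e-9, engine: RigidBodyEngine = None, forces=None,
                    max_iter=100):
    """Rotational velocity-Verlet step for rigid bodies (plus free atoms).

    The quaternion time derivative at the half step is obtained by
    self-consistent iteration converged to ``eps``; quaternions are
    renormalized every step.  Returns the force tuple at t+dt.
    """
    if engine is None:
        engine = RigidBodyEngine(topo)
    if forces is None:
        forces = force_fn(state.positions, state.radius)
    live = ~engine.frozen
    f_com, torque = engine.com_force_torque(state.positions, forces[1])

    # translations: half kick + drift
    state.body_vcom[live] += 0.5 * dt * ACC_UNIT * f_com[live] / engine.mass[live, None]
    state.body_com[live] += dt * state.body_vcom[live]

    # rotations: half kick on L, midpoint iteration for the quaternion
    l_half = state.body_angmom.copy()
    l_half[live] += 0.5 * dt * ACC_UNIT * torque[live]
    if engine.n_bodies:
        from . import _kernels
        q_new, n_fail = _kernels.rvv_rotation(
            state.body_quat, l_half, engine.inertia,
            live.astype(np.bool_), dt, eps, max_iter)
        if n_fail:
            raise RuntimeError(
                f"quaternion derivative iteration did not converge "
                f"for {n_fail} bodies")
        state.body_quat[live] = q_new[live]

    # free atoms drift
    free = engine.free_atoms
    if len(free):
        state.velocities[free] += 0.5 * dt * ACC_UNIT * forces[1][free] \
            / topo.masses[free, None]
        state.positions[free] += dt * state.velocities[free]
        _apply_rattle(state, topo, 1e-10)

    engine.rebuild_positions(state)
    out = force_fn(state.positions, state.radius)
    f_com, torque = engine.com_force_torque(state.positions, out[1])
    state.body_vcom[live] += 0.5 * dt * ACC_UNIT * f_com[live] / engine.mass[live, None]
    state.body_angmom[live] = l_half[live] + 0.5 * dt * ACC_UNIT * torque[live]
    if len(free):
        state.velocities[free] += 0.5 * dt * ACC_UNIT * out[1][free] \
            / topo.masses[free, None]
        _apply_rattle_velocities(state, topo, 1e-10)
    state.time += dt
    return out



# ---------------------------------------------------------------------------
# thermostat / pressure / barostat

def bussi_scale_factor(kinetic, ndof, params: ThermostatParams, dt, rng):
    """Canonical velocity-rescaling factor (one Gaussian + one chi-squared)."""
    if kinetic <= 0:
        raise ValueError("kinetic energy must be positive")
    k_target = 0.5 * ndof * KB * params.temperature
    x = math.exp(-dt / params.tau)
    r1 = rng.standard_normal()
    s = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
    c = k_target / (ndof * kinetic)
    a2 = x + c * (1.0 - x) * (r1 * r1 + s) + 2.0 * r1 * math.sqrt(c * x * (1.0 - x))
    return math.sqrt(max(a2, 0.0))


def bussi_thermostat(state: SystemState, topo: Topology, params: ThermostatParams,
                     dt, rng, engine: RigidBodyEngine = None):
    """Apply the stochastic rescaling to velocities and angular momenta."""
    if engine is None:
        engine = RigidBodyEngine(topo)
    kin, ndof = kinetic_energy(state, topo, engine)
    alpha = bussi_scale_factor(kin, ndof, params, dt, rng)
    if len(engine.free_atoms):
        state.velocities[engine.free_atoms] *= alpha
    live = ~engine.frozen
    state.body_vcom[live] *= alpha
    state.body_angmom[live] *= alpha
    return alpha


def kinetic_energy(state: SystemState, topo: Topology, engine: RigidBodyEngine):
    """Total kinetic energy (kJ/mol) and the number of degrees of freedom."""
    free = engine.free_atoms
    k_free = 0.5 * KE_UNIT * float(
        np.sum(topo.masses[free, None] * state.velocities[free]**2))
    live = ~engine.frozen
    k_trans = 0.5 * KE_UNIT * float(
        np.sum(engine.mass[live, None] * state.body_vcom[live]**2))
    k_rot = engine.rotational_energy(state)
    n_cons = sum(1 for i, j, d in topo.constraints if not topo.frozen[i])
    ndof = 3 * len(free) - n_cons + 6 * int(live.sum())
    return k_free + k_trans + k_rot, ndof


def translational_kinetic_energy(state, topo, engine):
    """COM translational kinetic energy of molecules (enters the pressure)."""
    live = ~engine.frozen
    k_trans = 0.5 * KE_UNIT * float(
        np.sum(engine.mass[live, None] * state.body_vcom[live]**2))
    free = engine.free_atoms
    if len(free):
        com_v = {}
        for a in free:
            com_v.setdefault(int(topo.molecule[a]), []).append(a)
        for mol, atoms in com_v.items():
            m = topo.masses[atoms]
            v = (m[:, None] * state.velocities[atoms]).sum(axis=0) / m.sum()
            k_trans += 0.5 * KE_UNIT * float(m.sum() * v @ v)
    return k_trans


def pressure(kinetic_trans, virial, volume, extra_dEdV=0.0):
    """Isotropic Clausius-virial pressure in bar.

    P = (2 E_kin + W) / (3V) - dE_solv/dV, with E_kin the molecular
    translational kinetic energy and W the molecular virial.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    p = (2.0 * kinetic_trans + virial) / (3.0 * volume) - extra_dEdV
    return p * PRESSURE_UNIT


def berendsen_scale(p_inst, params: BarostatParams, dt):
    """Weak-coupling scaling factor μ; coordinates and R scale by μ."""
    arg = 1.0 - params.alpha * params.compressibility * (dt / params.tau) \
        * (params.pressure - p_inst)
    mu = np.cbrt(arg)
    clamped = False
    if mu < 0.95:
        mu, clamped = 0.95, True
    elif mu > 1.05:
        mu, clamped = 1.05, True
    return mu, clamped


# ---------------------------------------------------------------------------
# driver

@dataclass
class SimulationConfig:
    ensemble: str = "NVT"           # NVE | NVT | NPT
    dt: float = 0.002               # ps
    n_steps: int = 1000
    temperature: float = 298.15
    tau_t: float = 0.4
    pressure: float = 1.0           # bar
    tau_p: float = 4.0
    compressibility: float = 4.5e-5
    alpha: float = 1.0
    radius: float = None            # Å; required
    reaction_field: bool = False
    lmax: int = 10
    grid_points: int = 302
    epsilon: float = None           # None -> conductor
    rf_in_pressure: bool = True
    wall: bool = True
    seed: int = 0
    traj_stride: int = 500
    log_stride: int = 10
    rvv_eps: float = 1e-9

    def __post_init__(self):
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.dt <= 0 or self.n_steps < 0:
            raise ValueError("dt must be positive and n_steps non-negative")
        if self.radius is None or self.radius <= 0:
            raise ValueError("a positive cavity radius is required")


@dataclass
class SimulationResult:
    frames: list                    # (time, radius, positions) tuples
    log: "object"                   # pandas DataFrame
    state: SystemState
    wall_events: int = 0


def maxwell_velocities(topo: Topology, engine: RigidBodyEngine, temperature, rng):
    """Maxwell–Boltzmann draw: COM velocities and angular momenta at T."""
    vel = np.zeros((topo.n_atoms, 3))
    free = engine.free_atoms
    if len(free):
        sd = np.sqrt(KB * temperature / (KE_UNIT * topo.masses[free]))
        vel[free] = rng.standard_normal((len(free), 3)) * sd[:, None]
    nb = engine.n_bodies
    vcom = np.zeros((nb, 3))
    angmom = np.zeros((nb, 3))
    if nb:
        live = ~engine.frozen
        sd = np.sqrt(KB * temperature / (KE_UNIT * engine.mass[live]))
        vcom[live] = rng.standard_normal((int(live.sum()), 3)) * sd[:, None]
        sd_l = np.sqrt(engine.inertia[live] * KB * temperature / KE_UNIT)
        l_body = rng.standard_normal((int(live.sum()), 3)) * sd_l
        angmom[live] = l_body  # converted to space frame by the caller
    return vel, vcom, angmom


class Simulation:
    """NVT/NPT/NVE driver: forces → step → wall → thermostat → barostat."""

    def __init__(self, topo: Topology, positions: np.ndarray,
                 config: SimulationConfig, meanfield: MeanFieldPotential = None):
        from .ddcosmo import ReactionFieldSolver, SphericalCavity
        from .sphere_grid import HarmonicBasis, build_lebedev_grid

        self.topo = topo
        self.config = config
        topo.initialize_bodies(positions)
        self.engine = RigidBodyEngine(topo)
        rf = None
        rf_factor = 1.0
        if config.reaction_field:
            rf = ReactionFieldSolver(HarmonicBasis(config.lmax),
                                     build_lebedev_grid(config.grid_points))
            if config.epsilon is not None:
                rf_factor = (config.epsilon - 1.0) / config.epsilon
        self.model = EnergyModel(topo, meanfield=meanfield, rf_solver=rf,
                                 rf_factor=rf_factor)
        rng = np.random.default_rng(config.seed)
        positions = project_virtual_sites(positions.copy(), topo)
        state = SystemState(
            time=0.0, positions=positions,
            velocities=np.zeros_like(positions), radius=config.radius, rng=rng)
        nb = self.engine.n_bodies
        if nb:
            state.body_com = np.zeros((nb, 3))
            state.body_quat = np.zeros((nb, 4))
            for ib, body in enumerate(topo.rigid_bodies):
                m = topo.masses[body.atoms]
                state.body_com[ib] = (m[:, None] * positions[body.atoms]).sum(0) / m.sum()
            # recover orientation from current coordinates: they were built
            # from body_coords by construction, so solve the Procrustes fit
            state.body_quat[:] = self._initial_quaternions(positions)
            state.body_vcom = np.zeros((nb, 3))
            state.body_angmom = np.zeros((nb, 3))
        vel, vcom, l_body = maxwell_velocities(topo, self.engine,
                                               config.temperature, rng)
        state.velocities = vel
        if nb:
            state.body_vcom = vcom
            A = quat_to_matrix(state.body_quat)
            state.body_angmom = np.einsum("nij,nj->ni", A, l_body)
            self.engine.rebuild_positions(state)
        project_virtual_sites(state.positions, topo)
        self.state = state
        self.forces = None
        self.wall_events = 0
        self.mu_clamped = 0

    def _initial_quaternions(self, positions):
        quats = np.empty((self.engine.n_bodies, 4))
        for ib, body in enumerate(self.topo.rigid_bodies):
            m = self.topo.masses[body.atoms]
            com = (m[:, None] * positions[body.atoms]).sum(0) / m.sum()
            rel = positions[body.atoms] - com
            H = body.body_coords.T @ (m[:, None] * rel)
            U, _, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            A = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T  # body -> space
            quats[ib] = _matrix_to_quat(A)
        return quats

    def _force_fn(self, positions, radius):
        energies, forces, virial, dEdV = self.model.evaluate(positions, radius)
        return energies, forces, virial, dEdV

    def step(self):
        cfg = self.config
        state = self.state
        if self.forces is None:
            self.forces = self._force_fn(state.positions, state.radius)
        self.forces = rigid_body_step(
            state, self.topo, self._force_fn, cfg.dt, eps=cfg.rvv_eps,
            engine=self.engine, forces=self.forces)
        if cfg.wall:
            before = self.forces
            n_ev = rough_wall(state, self.topo, state.radius,
                              cfg.temperature, state.rng)
            self.wall_events += n_ev
            self.forces = before
        if cfg.ensemble in ("NVT", "NPT"):
            bussi_thermostat(state, self.topo,
                             ThermostatParams(cfg.temperature, cfg.tau_t),
                             cfg.dt, state.rng, engine=self.engine)
        p_inst = None
        if cfg.ensemble == "NPT":
            k_trans = translational_kinetic_energy(state, self.topo, self.engine)
            volume = 4.0 / 3.0 * np.pi * state.radius**3
            dEdV = self.forces[3] if cfg.rf_in_pressure else 0.0
            p_inst = pressure(k_trans, self.forces[2], volume, dEdV)
            mu, clamped = berendsen_scale(
                p_inst,
                BarostatParams(cfg.pressure, cfg.tau_p, cfg.compressibility,
                               cfg.alpha), cfg.dt)
            self.mu_clamped += clamped
            self._scale(mu)
        return p_inst

    def _scale(self, mu):
        state = self.state
        state.radius *= mu
        live = ~self.engine.frozen
        state.body_com[live] *= mu
        self.engine.rebuild_positions(state)
        free = self.engine.free_atoms
        if len(free):
            com, _ = self.topo.molecule_com(state.positions)
            shift = (mu - 1.0) * com[self.topo.molecule[free]]
            state.positions[free] += shift
        project_virtual_sites(state.positions, self.topo)

    def run(self, n_steps=None, log_rows=None, frames=None):
        import pandas as pd
        cfg = self.config
        n_steps = cfg.n_steps if n_steps is None else n_steps
        log_rows = [] if log_rows is None else log_rows
        frames = [] if frames is None else frames
        for istep in range(1, n_steps + 1):
            p_inst = self.step()
            if istep % cfg.log_stride == 0:
                row = self._log_row(p_inst)
                if not np.isfinite(row["E_total"]):
                    raise FloatingPointError(
                        f"non-finite state at step {istep}")
                log_rows.append(row)
            if istep % cfg.traj_stride == 0:
                frames.append((self.state.time, self.state.radius,
                               self.state.positions.copy()))
        log = pd.DataFrame(log_rows)
        return SimulationResult(frames=frames, log=log, state=self.state,
                                wall_events=self.wall_events)

    def _log_row(self, p_inst=None):
        state, topo, engine = self.state, self.topo, self.engine
        kin, ndof = kinetic_energy(state, topo, engine)
        energies = self.forces[0]
        volume = 4.0 / 3.0 * np.pi * state.radius**3
        if p_inst is None:
            k_trans = translational_kinetic_energy(state, topo, engine)
            dEdV = self.forces[3] if self.config.rf_in_pressure else 0.0
            p_inst = pressure(k_trans, self.forces[2], volume, dEdV)
        row = {
            "time": state.time,
            "T": 2.0 * kin / (ndof * KB),
            "P": p_inst,
            "R": state.radius,
            "E_kin": kin,
            "E_total": kin + sum(energies.values()),
        }
        for key, val in energies.items():
            row[f"E_{key}"] = val
        return row


def _matrix_to_quat(A: np.ndarray) -> np.ndarray:
    """Rotation matrix (body->space) to a unit quaternion (w, x, y, z)."""
    tr = np.trace(A)
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2
        w = 0.25 * s
        x = (A[2, 1] - A[1, 2]) / s
        y = (A[0, 2] - A[2, 0]) / s
        z = (A[1, 0] - A[0, 1]) / s
    else:
        i = int(np.argmax(np.diag(A)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1.0 + A[i, i] - A[j, j] - A[k, k], 0.0)) * 2
        q = np.empty(3)
        q[i] = 0.25 * s
        q[j] = (A[j, i] + A[i, j]) / s
        q[k] = (A[k, i] + A[i, k]) / s
        w = (A[k, j] - A[j, k]) / s
        x, y, z = q
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def run_simulation(topo: Topology, positions: np.ndarray,
                   config: SimulationConfig,
                   meanfield: MeanFieldPotential = None) -> SimulationResult:
    """Build a :class:`Simulation` and run it for ``config.n_steps``."""
    sim = Simulation(topo, positions, config, meanfield=meanfield)
    return sim.run()
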