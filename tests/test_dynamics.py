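"""Integrators, constraints, thermostat, pressure and the driver."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from npbcmd.constants import ACC_UNIT, KB, KE_UNIT, PRESSURE_UNIT
from npbcmd.dynamics import (BarostatParams, RigidBodyEngine, Simulation,
                             SimulationConfig, SystemState, ThermostatParams,
                             berendsen_scale, bussi_scale_factor,
                             bussi_thermostat, kinetic_energy, pressure,
                             quat_to_matrix, rattle_project, rigid_body_step,
                             run_simulation, velocity_verlet_step)
from npbcmd.fixtures import SPC, BuildSpec, build_water_sphere, water_topology
from npbcmd.forcefield import RigidBody, Topology, pair_energy_forces


def free_topology(n, mass=10.0):
    return Topology(masses=np.full(n, mass), charges=np.zeros(n),
                    lj_sigma=np.zeros(n), lj_epsilon=np.zeros(n),
                    molecule=np.arange(n))


def make_state(pos, vel, radius=50.0):
    return SystemState(time=0.0, positions=np.asarray(pos, float),
                       velocities=np.asarray(vel, float), radius=radius)


def const_force_fn(f_vec):
    f_vec = np.asarray(f_vec, float)

    def fn(positions, radius):
        return {}, np.tile(f_vec, (len(positions), 1)), 0.0, 0.0
    return fn


class TestVelocityVerlet:
    def test_uniform_acceleration_exact(self):
        """Constant force: the trajectory is exactly quadratic in time."""
        topo = free_topology(1)
        state = make_state([[0.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]])
        fn = const_force_fn([0.0, 0.0, 2.0])
        dt = 0.01
        forces = None
        for _ in range(100):
            forces = velocity_verlet_step(state, topo, fn, dt, forces=forces)
        t = state.time
        a = ACC_UNIT * 2.0 / 10.0
        assert state.positions[0, 0] == pytest.approx(t, rel=1e-12)
        assert state.positions[0, 2] == pytest.approx(0.5 * a * t * t,
                                                      rel=1e-12)

    def test_harmonic_oscillator_energy_drift(self):
        k = 1.0
        m = 1.0
        omega = np.sqrt(ACC_UNIT * k / m)
        period = 2 * np.pi / omega
        dt = period / 100.0
        topo = free_topology(1, mass=m)
        state = make_state([[1.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]])

        def fn(positions, radius):
            return {}, -k * positions, 0.0, 0.0

        def total_energy():
            kin = 0.5 * KE_UNIT * m * np.sum(state.velocities**2)
            potential = 0.5 * k * np.sum(state.positions**2)
            return kin + potential

        e0 = total_energy()
        forces = None
        for _ in range(1000):
            forces = velocity_verlet_step(state, topo, fn, dt, forces=forces)
        assert abs(total_energy() - e0) / e0 < 1e-4

    def test_rattle_diatomic_bond_conserved(self):
        topo = Topology(masses=[2.0, 2.0], charges=[0.0, 0.0],
                        lj_sigma=np.zeros(2), lj_epsilon=np.zeros(2),
                        molecule=[0, 0], constraints=[(0, 1, 1.2)])
        state = make_state([[0.0, 0, 0], [1.2, 0, 0]],
                           [[0.0, 0.4, 0], [0.0, -0.4, 0.3]])
        fn = const_force_fn([0.0, 0.0, 0.0])
        forces = None
        for _ in range(10**4):
            forces = velocity_verlet_step(state, topo, fn, 0.001,
                                          forces=forces)
        bond = np.linalg.norm(state.positions[0] - state.positions[1])
        assert bond == pytest.approx(1.2, abs=1.2e-9)


class TestRattleProject:
    def test_satisfied_constraints_identity(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        vel = np.array([[0.2, 0.1, 0], [0.2, -0.1, 0]])
        p, v = rattle_project(pos.copy(), vel.copy(), [(0, 1, 1.0)],
                              np.array([1.0, 1.0]))
        assert np.allclose(p, pos, atol=1e-12)

    def test_stretched_bond_restored_momentum_conserved(self):
        masses = np.array([3.0, 1.0])
        pos = np.array([[0.0, 0, 0], [1.01, 0, 0]])
        vel = np.array([[0.5, 0, 0], [-0.1, 0, 0]])
        p_before = (masses[:, None] * vel).sum(0)
        com_before = (masses[:, None] * pos).sum(0) / masses.sum()
        p, v = rattle_project(pos, vel, [(0, 1, 1.0)], masses)
        assert np.linalg.norm(p[0] - p[1]) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose((masses[:, None] * v).sum(0), p_before)
        assert np.allclose((masses[:, None] * p).sum(0) / masses.sum(),
                           com_before)
        # relative velocity has no component along the bond
        assert abs(np.dot(p[0] - p[1], v[0] - v[1])) < 1e-10

    def test_water_triangle_all_satisfied(self):
        masses = np.array([16.0, 1.0, 1.0])
        cons = [(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.633)]
        rng = np.random.default_rng(0)
        pos = np.array([[0.0, 0, 0], [1.05, 0, 0], [-0.4, 0.93, 0]])
        vel = rng.normal(size=(3, 3))
        p, v = rattle_project(pos, vel, cons, masses)
        for i, j, d in cons:
            assert np.linalg.norm(p[i] - p[j]) == pytest.approx(d, abs=1e-9)
            assert abs(np.dot(p[i] - p[j], v[i] - v[j])) < 1e-9


def rigid_top_topology(coords, masses):
    n = len(masses)
    topo = Topology(masses=masses, charges=np.zeros(n),
                    lj_sigma=np.zeros(n), lj_epsilon=np.zeros(n),
                    molecule=np.zeros(n, dtype=int),
                    rigid_bodies=[RigidBody(atoms=np.arange(n))])
    topo.initialize_bodies(np.asarray(coords, float))
    return topo


def body_state(topo, angmom):
    body = topo.rigid_bodies[0]
    pos = body.body_coords.copy()
    return SystemState(time=0.0, positions=pos,
                       velocities=np.zeros_like(pos), radius=50.0,
                       body_com=np.zeros((1, 3)),
                       body_vcom=np.zeros((1, 3)),
                       body_quat=np.array([[1.0, 0, 0, 0]]),
                       body_angmom=np.array([angmom], dtype=float))


def zero_force(positions, radius):
    return {}, np.zeros_like(positions), 0.0, 0.0


class TestRigidBodyIntegrator:
    def test_torque_free_symmetric_top(self):
        # square of four masses: I_z = 2 I_x = 2 I_y
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0],
                           [0, 1.0, 0], [0, -1.0, 0]])
        topo = rigid_top_topology(coords, np.full(4, 2.0))
        engine = RigidBodyEngine(topo)
        state = body_state(topo, [5.0, 0.0, 12.0])
        e0 = engine.rotational_energy(state)
        l0 = state.body_angmom[0].copy()
        forces = None
        for _ in range(10**4):
            forces = rigid_body_step(state, topo, zero_force, 0.001,
                                     engine=engine, forces=forces)
        assert np.abs(state.body_angmom[0] - l0).max() < 1e-9
        assert engine.rotational_energy(state) == pytest.approx(e0, rel=1e-8)

    def test_torque_free_asymmetric_top_polhode(self):
        """Body-frame L follows the Euler equations (reference integration)."""
        coords = np.array([[1.5, 0, 0], [-1.5, 0, 0],
                           [0, 0.9, 0], [0, -0.9, 0],
                           [0, 0, 0.4], [0, 0, -0.4]])
        masses = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        topo = rigid_top_topology(coords, masses)
        engine = RigidBodyEngine(topo)
        inertia = engine.inertia[0]
        l_body0 = np.array([4.0, 3.0, 2.0])
        # initial quaternion is the identity: body frame = space frame
        state = body_state(topo, l_body0)
        e0 = engine.rotational_energy(state)

        def euler(t, l):
            omega = l / inertia
            return np.cross(l, omega)

        t_end = 1.0
        ref = solve_ivp(euler, (0, t_end), l_body0, rtol=1e-12, atol=1e-12)
        forces = None
        for _ in range(1000):
            forces = rigid_body_step(state, topo, zero_force, 0.001,
                                     engine=engine, forces=forces)
        A = quat_to_matrix(state.body_quat)[0]
        l_body = A.T @ state.body_angmom[0]
        assert np.linalg.norm(state.body_angmom[0] - l_body0) < 1e-9
        assert engine.rotational_energy(state) == pytest.approx(e0, rel=1e-8)
        assert np.abs(l_body - ref.y[:, -1]).max() < 1e-3 * np.linalg.norm(l_body0)

    def test_zero_angular_momentum_orientation_constant(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.5, 0],
                           [0, -1.5, 0]])
        topo = rigid_top_topology(coords, np.full(4, 1.0))
        state = body_state(topo, [0.0, 0.0, 0.0])
        engine = RigidBodyEngine(topo)
        forces = None
        for _ in range(100):
            forces = rigid_body_step(state, topo, zero_force, 0.002,
                                     engine=engine, forces=forces)
        assert np.allclose(state.body_quat[0], [1.0, 0, 0, 0], atol=1e-12)


class _QuietRng:
    """Noise draws replaced by their means: E[r1] = 0, E[r1² + χ²_{N-1}] = N."""

    def standard_normal(self):
        return 0.0

    def chisquare(self, df):
        return float(df) + 1.0


class TestBussiThermostat:
    def test_decoupled_limit_scale_is_one(self):
        rng = np.random.default_rng(0)
        params = ThermostatParams(300.0, tau=1e12)
        a = bussi_scale_factor(100.0, 300, params, 0.002, rng)
        assert a == pytest.approx(1.0, abs=1e-6)

    def test_fixed_point_at_target_kinetic_energy(self):
        ndof = 150
        k_target = 0.5 * ndof * KB * 300.0
        a = bussi_scale_factor(k_target, ndof, ThermostatParams(300.0, 0.4),
                               0.002, _QuietRng())
        assert a == pytest.approx(1.0, rel=1e-12)

    def test_canonical_kinetic_energy_distribution(self):
        """Stationary K samples follow the gamma(N_dof/2, k_B T) law."""
        n = 50
        ndof = 3 * n
        temperature = 300.0
        topo = free_topology(n, mass=18.0)
        rng = np.random.default_rng(42)
        sd = np.sqrt(KB * temperature / (KE_UNIT * 18.0))
        state = make_state(np.zeros((n, 3)), rng.standard_normal((n, 3)) * sd)
        engine = RigidBodyEngine(topo)
        params = ThermostatParams(temperature, tau=0.1)
        samples = []
        for i in range(20000):
            bussi_thermostat(state, topo, params, 0.002, rng, engine=engine)
            if i % 100 == 0:
                k, _ = kinetic_energy(state, topo, engine)
                samples.append(k)
        shape = ndof / 2.0
        scale = KB * temperature
        stat, p = stats.kstest(samples, "gamma", args=(shape, 0.0, scale))
        assert p > 0.01


class TestPressure:
    def test_ideal_gas_law_recovered(self):
        n, t = 64, 298.15
        kin = 1.5 * n * KB * t
        volume = 4.0 / 3.0 * np.pi * 10.0**3
        p = pressure(kin, 0.0, volume)
        assert p == pytest.approx(n * KB * t / volume * PRESSURE_UNIT,
                                  rel=1e-12)

    def test_volume_must_be_positive(self):
        with pytest.raises(ValueError):
            pressure(1.0, 0.0, 0.0)

    def test_lj_virial_against_scaling_derivative(self):
        """W = -3V dU/dV under uniform coordinate scaling."""
        rng = np.random.default_rng(7)
        n = 10
        topo = Topology(masses=np.full(n, 10.0), charges=np.zeros(n),
                        lj_sigma=np.full(n, 3.0), lj_epsilon=np.full(n, 0.5),
                        molecule=np.arange(n))
        pos = rng.uniform(-4.5, 4.5, (n, 3))
        _, _, w = pair_energy_forces(pos, topo)
        lam = 1e-6
        ep = pair_energy_forces(pos * (1 + lam), topo)[0]
        em = pair_energy_forces(pos * (1 - lam), topo)[0]
        radius = 8.0
        volume = 4.0 / 3.0 * np.pi * radius**3
        dU_dV = (ep - em) / (2 * lam) / (3.0 * volume)
        assert w == pytest.approx(-3.0 * volume * dU_dV, rel=1e-2)


class TestBerendsen:
    def test_equilibrium_fixed_point(self):
        mu, clamped = berendsen_scale(1000.0, BarostatParams(1000.0), 0.002)
        assert mu == 1.0 and not clamped

    def test_expands_under_excess_pressure(self):
        mu, _ = berendsen_scale(2000.0, BarostatParams(1000.0), 0.002)
        assert mu > 1.0

    def test_plug_in_value(self):
        params = BarostatParams(pressure=0.0, tau=4.0, compressibility=4.5e-5,
                                alpha=1.0)
        # P0 - P = -1000 bar
        mu, _ = berendsen_scale(1000.0, params, 0.002)
        assert mu == pytest.approx((1 + 2.25e-5) ** (1.0 / 3.0), rel=1e-12)

    def test_runaway_clamped(self):
        params = BarostatParams(pressure=0.0, tau=0.01, compressibility=4.5e-3)
        mu, clamped = berendsen_scale(1e6, params, 0.002)
        assert mu == 1.05 and clamped


class TestDriver:
    def test_cold_single_molecule_stays_at_rest(self):
        topo = water_topology(SPC, 1)
        pos = SPC.site_coords()
        config = SimulationConfig(ensemble="NVE", dt=0.002, n_steps=50,
                                  radius=8.5, temperature=1e-12, seed=0,
                                  wall=False, log_stride=10, traj_stride=1000)
        result = run_simulation(topo, pos.copy(), config)
        assert np.abs(result.state.positions - pos).max() < 1e-7

    def test_nve_energy_conservation_rigid_water(self):
        pos, topo = build_water_sphere(BuildSpec(model="SPC", radius=6.0,
                                                 seed=11))
        config = SimulationConfig(ensemble="NVE", dt=0.001, n_steps=10000,
                                  radius=6.0, temperature=298.15, seed=12,
                                  wall=False, log_stride=100,
                                  traj_stride=10**9)
        result = run_simulation(topo, pos.copy(), config)
        e = result.log["E_total"].to_numpy()
        kin = result.log["E_kin"].mean()
        assert abs(e[-1] - e[0]) / kin < 1e-3

    def test_trajectory_determinism(self):
        pos, topo = build_water_sphere(BuildSpec(model="SPC", radius=6.0,
                                                 seed=13))
        config = SimulationConfig(ensemble="NVT", dt=0.002, n_steps=200,
                                  radius=6.0, temperature=298.15, seed=14,
                                  log_stride=50, traj_stride=10**9)
        r1 = run_simulation(topo, pos.copy(), config)
        r2 = run_simulation(topo, pos.copy(), config)
        assert np.array_equal(r1.state.positions, r2.state.positions)
        config2 = SimulationConfig(ensemble="NVT", dt=0.002, n_steps=200,
                                   radius=6.0, temperature=298.15, seed=15,
                                   log_stride=50, traj_stride=10**9)
        r3 = run_simulation(topo, pos.copy(), config2)
        assert not np.array_equal(r1.state.positions, r3.state.positions)

    def test_npt_ideal_gas_relaxes_to_gas_law_volume(self):
        """R approaches the root of N k_B T / V = P0."""
        n, temperature, p0 = 100, 298.15, 1000.0
        rng = np.random.default_rng(3)
        topo = free_topology(n, mass=30.0)
        pos = rng.uniform(-6, 6, (n, 3))
        pos = pos[np.linalg.norm(pos, axis=1) < 11.0]
        topo = free_topology(len(pos), mass=30.0)
        config = SimulationConfig(ensemble="NPT", dt=0.002, n_steps=10000,
                                  radius=12.0, temperature=temperature,
                                  tau_t=0.2, pressure=p0, tau_p=0.5,
                                  compressibility=1e-3, seed=4,
                                  log_stride=100, traj_stride=10**9)
        result = run_simulation(topo, pos.copy(), config)
        v_target = len(pos) * KB * temperature * PRESSURE_UNIT / p0
        r_target = (3 * v_target / (4 * np.pi)) ** (1.0 / 3.0)
        r_traj = result.log["R"].to_numpy()
        assert abs(r_traj[-1] - r_target) / r_target < 0.05
        # overall monotone approach: R decreases toward the fixed point
        assert r_traj[0] > r_traj[len(r_traj) // 2] > r_traj[-1] - 0.5
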