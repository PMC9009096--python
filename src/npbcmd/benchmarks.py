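"""Desk-scale benchmark protocols on the 8.5 Å water sphere.

These drive the full engine end to end: an NPT run whose sampled pressure
must center on the barostat set-point, and paired NVT runs (vacuum vs
conductor reaction field at the boundary) whose first-peak O-O g(r) widths
quantify boundary-induced overstructuring.
"""

import numpy as np

from .analysis import hwhm_first_peak, rdf_npbc
from .dynamics import Simulation, SimulationConfig
from .fixtures import BuildSpec, build_water_sphere

RADIUS = 8.5
DT = 0.002
TEMPERATURE = 298.15


def npt_pressure_benchmark(seed: int, n_steps: int = 60000,
                           equilibration_ps: float = 20.0):
    """NPT TIP3P-FB sphere at a 1000 bar set-point.

    Returns ``(mean pressure bar, n samples, block-averaged SE)``.
    """
    pos, topo = build_water_sphere(
        BuildSpec(model="TIP3P-FB", radius=RADIUS, density=0.997, seed=seed))
    config = SimulationConfig(
        ensemble="NPT", dt=DT, n_steps=n_steps, radius=RADIUS,
        temperature=TEMPERATURE, tau_t=0.4, pressure=1000.0, tau_p=4.0,
        compressibility=4.5e-5, seed=seed + 1, log_stride=5,
        traj_stride=10**9)
    sim = Simulation(topo, pos.copy(), config)
    result = sim.run()
    log = result.log
    prod = log[log["time"] > equilibration_ps]
    p = prod["P"].to_numpy()
    n_blocks = max(len(p) // 200, 2)  # 2 ps blocks against autocorrelation
    blocks = np.array_split(p, n_blocks)
    means = np.array([b.mean() for b in blocks])
    sem = means.std(ddof=1) / np.sqrt(len(means))
    return float(p.mean()), len(p), float(sem)


def boundary_hwhm_benchmark(seed: int, reaction_field: bool,
                            n_steps: int = 110000,
                            equilibration_ps: float = 20.0):
    """NVT SPC sphere; first-peak O-O g(r) HWHM.

    Centers restricted to 4.5 Å, neighbors to 4.0 Å, 0.05 Å bins.
    Returns ``(hwhm Å, n frames, peak position Å)``.
    """
    pos, topo = build_water_sphere(
        BuildSpec(model="SPC", radius=RADIUS, density=0.997, seed=seed))
    config = SimulationConfig(
        ensemble="NVT", dt=DT, n_steps=n_steps, radius=RADIUS,
        temperature=TEMPERATURE, tau_t=0.4, reaction_field=reaction_field,
        lmax=10, grid_points=302, seed=seed + 2 + int(reaction_field),
        log_stride=100, traj_stride=250)
    sim = Simulation(topo, pos.copy(), config)
    result = sim.run()
    frames = [f for f in result.frames if f[0] > equilibration_ps]
    oxygens = np.array([i for i, e in enumerate(topo.elements) if e == "O"])
    rdf = rdf_npbc(frames, oxygens, oxygens, r_sel=4.5, r_max=4.0,
                   bin_width=0.05, exclude_same_molecule=topo.molecule)
    pos_peak, hwhm = hwhm_first_peak(rdf)
    return float(hwhm), len(frames), float(pos_peak)
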