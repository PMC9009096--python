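"""Structural observables on nonperiodic (spherical-cavity) trajectories.

Radial distribution functions use the finite-sphere normalization: central
atoms are restricted to a ball of radius ``r_sel`` around the center so
that every neighbor shell up to ``r_max`` lies entirely inside the cavity,
and ideal-gas counts use the global number density of the sphere.  Shell
density profiles use equal-volume concentric shells.  Hydrogen bonding is
measured by a continuous strength function (product of logistic switches
in the H···acceptor distance and the D-H···A angle).

A trajectory is a sequence of ``(time, radius, positions)`` frames, as
produced by :class:`npbcmd.dynamics.Simulation`.
"""

from dataclasses import dataclass, field as dfield

import numpy as np

__all__ = [
    "RDFResult", "HBondParams", "rdf_npbc", "hwhm_first_peak",
    "shell_density", "equal_volume_edges", "f_hb",
]


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g: np.ndarray
    r_sel: float
    r_max: float
    n_frames: int
    bin_width: float


def rdf_npbc(frames, centers, partners, r_sel, r_max, bin_width=0.05,
             exclude_same_molecule=None):
    """g(r) for a finite sphere.

    ``centers``/``partners`` are atom index arrays.  Central atoms are the
    subset of ``centers`` within ``r_sel`` of the cavity center in each
    frame; all partners up to ``r_max`` are histogrammed.  Identical atom
    indices are always excluded; pass a molecule-id array via
    ``exclude_same_molecule`` to drop intramolecular pairs as well.
    Normalization: ideal-gas counts at the global partner density
    N_partner / (4/3 π R³), frame by frame.
    """
    centers = np.asarray(centers, dtype=int)
    partners = np.asarray(partners, dtype=int)
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:]**3 - edges[:-1]**3)
    counts = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    n_frames = 0
    for time, radius, pos in frames:
        if r_sel + r_max > radius + 1e-9:
            raise ValueError(
                f"selection geometry violates the cavity: r_sel + r_max = "
                f"{r_sel + r_max:.3f} Å > R = {radius:.3f} Å")
        n_frames += 1
        cpos = pos[centers]
        central = centers[np.linalg.norm(cpos, axis=1) <= r_sel]
        if len(central) == 0:
            continue
        d = np.linalg.norm(pos[central][:, None, :] - pos[partners][None, :, :],
                           axis=2)
        mask = central[:, None] != partners[None, :]
        if exclude_same_molecule is not None:
            mol = np.asarray(exclude_same_molecule)
            mask &= mol[central][:, None] != mol[partners][None, :]
        d = d[mask]
        d = d[d < r_max]
        counts += np.histogram(d, bins=edges)[0]
        rho = len(partners) / (4.0 / 3.0 * np.pi * radius**3)
        expected += len(central) * rho * shell_vol
    if n_frames == 0:
        raise ValueError("no frames supplied")
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RDFResult(bin_centers=0.5 * (edges[:-1] + edges[1:]), g=g,
                     r_sel=r_sel, r_max=r_max, n_frames=n_frames,
                     bin_width=bin_width)


def hwhm_first_peak(rdf: RDFResult):
    """First-peak position and left-side half width at half maximum.

    The peak position is refined parabolically from the maximal bin; the
    baseline is the minimum of g to the left of the peak (zero when the
    peak rises straight from the origin); the half-height crossing is
    linearly interpolated between bins.  Raises on a peak-free profile.
    """
    g = rdf.g
    r = rdf.bin_centers
    i = int(np.argmax(g))
    if i == 0 or i == len(g) - 1 or g[i] <= 0:
        raise ValueError("no resolvable first peak in g(r)")
    denom = g[i + 1] - 2.0 * g[i] + g[i - 1]
    if denom >= 0 or np.all(np.diff(g) >= 0) or np.all(np.diff(g) <= 0):
        raise ValueError("no resolvable first peak in g(r)")
    shift = 0.5 * (g[i - 1] - g[i + 1]) / denom
    pos = r[i] + shift * rdf.bin_width
    height = g[i] - 0.25 * (g[i - 1] - g[i + 1]) * shift
    base = float(g[:i].min()) if i > 0 else 0.0
    half = base + 0.5 * (height - base)
    j = i
    while j > 0 and g[j - 1] > half:
        j -= 1
    if j == 0 and g[0] > half:
        raise ValueError("half height is never reached left of the peak")
    # linear interpolation between bins j-1 and j
    r_half = r[j - 1] + (half - g[j - 1]) / (g[j] - g[j - 1]) * rdf.bin_width \
        if j > 0 else r[0]
    return float(pos), float(pos - r_half)


def equal_volume_edges(radius: float, n_shells: int) -> np.ndarray:
    """Radii r_i = R·(i/n)^(1/3) bounding n equal-volume concentric shells."""
    return radius * (np.arange(n_shells + 1) / n_shells) ** (1.0 / 3.0)


def shell_density(frames, topo, n_shells: int, mode: str = "constant-volume"):
    """Per-shell mass density (g/cm³): mean and std over frames.

    Molecules are assigned to shells by their COM (each molecule counts in
    exactly one shell).  Returns (edges of the last frame, mean, std).
    """
    from .constants import AVOGADRO_VOL
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    if mode != "constant-volume":
        raise ValueError(f"unknown shell mode {mode!r}")
    per_frame = []
    edges = None
    for time, radius, pos in frames:
        edges = equal_volume_edges(radius, n_shells)
        com, mmass = topo.molecule_com(pos)
        rr = np.linalg.norm(com, axis=1)
        idx = np.clip(np.searchsorted(edges, rr, side="right") - 1,
                      0, n_shells - 1)
        mass_in = np.bincount(idx, weights=mmass, minlength=n_shells)
        vol = 4.0 / 3.0 * np.pi * (edges[1:]**3 - edges[:-1]**3)
        per_frame.append(mass_in / (AVOGADRO_VOL * vol))
    arr = np.asarray(per_frame)
    return edges, arr.mean(axis=0), arr.std(axis=0)


@dataclass
class HBondParams:
    """Continuous hydrogen-bond switches.

    S_r(r) = 1/(1+e^{a(r-r0)}) on the H···acceptor distance and
    S_θ(θ) = 1/(1+e^{-b(θ-θ0)}) on the D-H···A angle (degrees); each pair
    contributes S_r·S_θ ∈ [0, 1].
    """

    donors: np.ndarray = None        # (n, 2) array of (D, H) atom indices
    acceptors: np.ndarray = None     # acceptor atom indices
    r0: float = 2.5                  # Å
    a: float = 10.0                  # Å⁻¹
    theta0: float = 140.0            # deg
    b: float = 0.1                   # deg⁻¹

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("switch steepnesses must be positive")


def f_hb(positions, params: HBondParams, molecule=None):
    """Total continuous hydrogen-bond strength of one frame.

    Returns ``(total, per_pair)`` with per_pair of shape
    (n_donors, n_acceptors).  Pairs within the same molecule are excluded
    when a molecule-id array is given.
    """
    donors = np.asarray(params.donors, dtype=int)
    acceptors = np.asarray(params.acceptors, dtype=int)
    d_pos = positions[donors[:, 0]]
    h_pos = positions[donors[:, 1]]
    a_pos = positions[acceptors]
    ha = a_pos[None, :, :] - h_pos[:, None, :]
    r = np.linalg.norm(ha, axis=2)
    hd = d_pos - h_pos
    hd_norm = np.linalg.norm(hd, axis=1)
    cosang = np.einsum("ija,ia->ij", ha, hd) / np.maximum(r * hd_norm[:, None],
                                                          1e-12)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    s_r = 1.0 / (1.0 + np.exp(params.a * (r - params.r0)))
    s_t = 1.0 / (1.0 + np.exp(-params.b * (theta - params.theta0)))
    per_pair = s_r * s_t
    if molecule is not None:
        mol = np.asarray(molecule)
        same = mol[donors[:, 1]][:, None] == mol[acceptors][None, :]
        per_pair = np.where(same, 0.0, per_pair)
    return float(per_pair.sum()), per_pair
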