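"""Conductor-like reaction field of a single spherical cavity.

The apparent surface charge (ASC) of the conductor model is diagonal in
spherical harmonics for a single sphere: expanding the solute potential on
the boundary Γ as Φ(R·s) = Σ φ_lm Y_lm(s), the surface charge density
σ(R·s) = Σ σ_lm Y_lm(s) that cancels Φ on Γ is

    σ_lm = -f(ε) · (2l+1) / (4π k_e R) · φ_lm ,

with f = 1 in conductor mode and f(ε) = (ε-1)/ε in scaled mode.  The
solvation energy is E = R²/2 · Σ σ_lm φ_lm ≤ 0.

Discretization: φ_lm is computed by Lebedev quadrature of Φ over Γ, and σ
is represented by point charges Q_n = 4π w_n R² σ(R s_n) at the quadrature
nodes.  Energy, atomic forces and the cavity-volume derivative all use this
one discretization, so the analytic forces equal the exact derivatives of
the discrete energy (finite-difference consistent at fixed grid and L_max).
"""

from dataclasses import dataclass

import numpy as np

from .constants import KE_COULOMB
from .sphere_grid import HarmonicBasis, LebedevGrid, sph_harm_matrix
from . import _kernels

__all__ = [
    "SphericalCavity",
    "ChargeDistribution",
    "HarmonicCoeffs",
    "ReactionFieldResult",
    "ReactionFieldSolver",
    "potential_coeffs",
    "solve_asc",
    "solvation_energy",
    "forces",
    "energy_volume_derivative",
]


@dataclass
class SphericalCavity:
    """Spherical cavity of radius ``radius`` (Å) centered at ``center``."""

    center: np.ndarray
    radius: float
    dielectric_mode: str = "conductor"  # "conductor" | "scaled"
    epsilon: float | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")
        if self.dielectric_mode == "scaled":
            if self.epsilon is None or self.epsilon <= 1:
                raise ValueError("scaled mode requires epsilon > 1")
        elif self.dielectric_mode != "conductor":
            raise ValueError(f"unknown dielectric mode {self.dielectric_mode!r}")

    @property
    def dielectric_factor(self) -> float:
        if self.dielectric_mode == "conductor":
            return 1.0
        return (self.epsilon - 1.0) / self.epsilon

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class ChargeDistribution:
    """Point charges q_k (e) at positions r_k (Å), fully inside the cavity."""

    charges: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")

    def validate_inside(self, cavity: SphericalCavity) -> None:
        r = np.linalg.norm(self.positions - cavity.center, axis=1)
        if np.any(r >= cavity.radius):
            raise ValueError(
                "charge distribution must be fully inside the cavity; "
                f"max |r - center| = {r.max():.6g} >= R = {cavity.radius:.6g}"
            )


@dataclass
class HarmonicCoeffs:
    """Expansion coefficients of the boundary potential and the ASC."""

    phi_lm: np.ndarray
    sigma_lm: np.ndarray | None = None


@dataclass
class ReactionFieldResult:
    energy: float                 # kJ/mol
    forces: np.ndarray            # kJ/mol/Å, per atom
    dE_dV: float                  # kJ/mol/Å³


class ReactionFieldSolver:
    """Precomputed single-sphere ddCOSMO solver.

    Caches the harmonics matrix at the (radius-independent) unit-sphere
    nodes so repeated evaluations during MD — including a breathing cavity
    — only pay for the charge sums.
    """

    def __init__(self, basis: HarmonicBasis, grid: LebedevGrid):
        self.basis = basis
        self.grid = grid
        # (N_g, n_lm) harmonics at the nodes and quadrature-weighted copy
        self.Y = sph_harm_matrix(basis, grid.points)
        self.Yw = 4.0 * np.pi * grid.weights[:, None] * self.Y
        l = basis.l_of()
        self._two_l_plus_1 = 2.0 * l + 1.0

    # -- spectral pieces ---------------------------------------------------
    def potential_coeffs(self, dist: ChargeDistribution,
                         cavity: SphericalCavity, *, validate: bool = True) -> np.ndarray:
        if validate:
            dist.validate_inside(cavity)
        nodes = cavity.center + cavity.radius * self.grid.points
        phi_nodes = KE_COULOMB * _kernels.potential_at_points(
            nodes, dist.positions, dist.charges)
        return self.Yw.T @ phi_nodes

    def solve_asc(self, phi_lm: np.ndarray, cavity: SphericalCavity) -> np.ndarray:
        if not np.all(np.isfinite(phi_lm)):
            raise ValueError("phi_lm must be finite")
        f = cavity.dielectric_factor
        return -f * self._two_l_plus_1 * phi_lm / (4.0 * np.pi * KE_COULOMB * cavity.radius)

    def node_charges(self, sigma_lm: np.ndarray, cavity: SphericalCavity) -> np.ndarray:
        """Discrete surface charges Q_n = 4π w_n R² σ(R s_n)  (e)."""
        sigma_nodes = self.Y @ sigma_lm
        return 4.0 * np.pi * self.grid.weights * cavity.radius**2 * sigma_nodes

    # -- observables -------------------------------------------------------
    def energy(self, dist: ChargeDistribution, sigma_lm: np.ndarray,
               cavity: SphericalCavity, *, validate: bool = True) -> float:
        if validate:
            dist.validate_inside(cavity)
        Q = self.node_charges(sigma_lm, cavity)
        nodes = cavity.center + cavity.radius * self.grid.points
        phi_nodes = KE_COULOMB * _kernels.potential_at_points(
            nodes, dist.positions, dist.charges)
        return 0.5 * float(Q @ phi_nodes)

    def forces(self, dist: ChargeDistribution, sigma_lm: np.ndarray,
               cavity: SphericalCavity) -> np.ndarray:
        Q = self.node_charges(sigma_lm, cavity)
        nodes = cavity.center + cavity.radius * self.grid.points
        field = KE_COULOMB * _kernels.field_at_points(dist.positions, nodes, Q)
        return dist.charges[:, None] * field

    def dE_dV(self, dist: ChargeDistribution, sigma_lm: np.ndarray,
              cavity: SphericalCavity) -> float:
        R = cavity.radius
        Q = self.node_charges(sigma_lm, cavity)
        nodes = cavity.center + R * self.grid.points
        phi_nodes = KE_COULOMB * _kernels.potential_at_points(
            nodes, dist.positions, dist.charges)
        energy = 0.5 * float(Q @ phi_nodes)
        # field of the solute's charges at the cavity boundary; ∇Φ = -field
        field = KE_COULOMB * _kernels.field_at_points(nodes, dist.positions, dist.charges)
        radial = np.einsum("ni,ni->n", field, self.grid.points)
        dE_dR = energy / R - float(Q @ radial)
        return dE_dR / (4.0 * np.pi * R**2)

    def compute(self, dist: ChargeDistribution, cavity: SphericalCavity,
                *, validate: bool = True) -> ReactionFieldResult:
        phi = self.potential_coeffs(dist, cavity, validate=validate)
        sigma = self.solve_asc(phi, cavity)
        return ReactionFieldResult(
            energy=self.energy(dist, sigma, cavity, validate=False),
            forces=self.forces(dist, sigma, cavity),
            dE_dV=self.dE_dV(dist, sigma, cavity),
        )


# ---------------------------------------------------------------------------
# functional surface mirroring the solver, convenient for one-shot use

def _solver(basis: HarmonicBasis, grid: LebedevGrid) -> ReactionFieldSolver:
    return ReactionFieldSolver(basis, grid)


def potential_coeffs(dist, cavity, grid, basis) -> np.ndarray:
    """Quadrature expansion φ_lm of the solute potential on Γ."""
    if grid.order < 2 * basis.L_max:
        raise ValueError(
            f"grid precision {grid.order} < 2·L_max = {2 * basis.L_max}; "
            "use a finer Lebedev rule")
    return _solver(basis, grid).potential_coeffs(dist, cavity)


def solve_asc(phi_lm, cavity, basis=None) -> np.ndarray:
    """Diagonal per-(l,m) COSMO solve for the ASC coefficients."""
    phi_lm = np.asarray(phi_lm, dtype=float)
    if basis is None:
        L = int(round(np.sqrt(len(phi_lm)))) - 1
        basis = HarmonicBasis(L)
    if basis.n_funcs != len(phi_lm):
        raise ValueError("phi_lm length does not match the basis")
    l = basis.l_of()
    f = cavity.dielectric_factor
    return -f * (2.0 * l + 1.0) * phi_lm / (4.0 * np.pi * KE_COULOMB * cavity.radius)


def solvation_energy(dist, sigma_lm, cavity, grid) -> float:
    """One-half interaction of the ASC with the solute potential over Γ."""
    basis = HarmonicBasis(int(round(np.sqrt(len(sigma_lm)))) - 1)
    if basis.n_funcs != len(sigma_lm):
        raise ValueError("sigma_lm length is not a perfect square count")
    return _solver(basis, grid).energy(dist, np.asarray(sigma_lm, float), cavity)


def forces(dist, sigma_lm, cavity, grid) -> np.ndarray:
    """Force on each charge: q_k times the field of the discrete ASC."""
    basis = HarmonicBasis(int(round(np.sqrt(len(sigma_lm)))) - 1)
    return _solver(basis, grid).forces(dist, np.asarray(sigma_lm, float), cavity)


def energy_volume_derivative(dist, sigma_lm, cavity, grid) -> float:
    """Analytic dE/dV of the discretized solvation energy (V = 4/3 π R³)."""
    basis = HarmonicBasis(int(round(np.sqrt(len(sigma_lm)))) - 1)
    return _solver(basis, grid).dE_dV(dist, np.asarray(sigma_lm, float), cavity)
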