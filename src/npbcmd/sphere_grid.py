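"""Real spherical harmonics and Lebedev–Laikov quadrature on the unit sphere.

Conventions
-----------
Real orthonormal spherical harmonics: ∫ Y_lm Y_l'm' dΩ = δ_ll' δ_mm'.
Flat index map: ``idx = l*(l+1) + m`` with m = -l..l, so a basis truncated
at L_max has (L_max+1)² functions.

Lebedev–Laikov grids are taken from :func:`scipy.integrate.lebedev_rule`;
weights are renormalized to sum to 1, so a surface integral is
``4π · Σ_n w_n f(s_n)``.
"""

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import lebedev_rule
from scipy.special import sph_harm_y

__all__ = [
    "LebedevGrid",
    "HarmonicBasis",
    "LEBEDEV_SIZES",
    "build_lebedev_grid",
    "eval_real_sph_harm",
    "sph_harm_matrix",
]

#: supported grid sizes -> algebraic precision order of the rule
#: (rules with negative weights, e.g. 74/230/266 points, are excluded)
LEBEDEV_SIZES = {
    6: 3, 14: 5, 26: 7, 38: 9, 50: 11, 86: 15, 110: 17,
    146: 19, 170: 21, 194: 23, 302: 29, 350: 31, 434: 35, 590: 41,
}


@dataclass(frozen=True)
class HarmonicBasis:
    """Real orthonormal spherical-harmonic basis truncated at ``L_max``."""

    L_max: int
    convention: str = "real-orthonormal"

    def __post_init__(self):
        if self.L_max < 0:
            raise ValueError(f"L_max must be >= 0, got {self.L_max}")

    @property
    def n_funcs(self) -> int:
        return (self.L_max + 1) ** 2

    def l_of(self) -> np.ndarray:
        """Degree l for each flat index."""
        return np.repeat(np.arange(self.L_max + 1), 2 * np.arange(self.L_max + 1) + 1)


@dataclass(frozen=True)
class LebedevGrid:
    """A Lebedev–Laikov quadrature rule on the unit sphere.

    ``order`` is the algebraic precision: the rule integrates spherical
    polynomials of degree <= order exactly.  Weights sum to one.
    """

    order: int
    points: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        norms = np.linalg.norm(self.points, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("Lebedev points must lie on the unit sphere")
        if np.any(self.weights <= 0):
            raise ValueError("Lebedev weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("Lebedev weights must sum to 1")

    @property
    def size(self) -> int:
        return len(self.weights)


@lru_cache(maxsize=None)
def build_lebedev_grid(requested_points: int) -> LebedevGrid:
    """Return the Lebedev grid with exactly ``requested_points`` nodes.

    Raises ``ValueError`` listing the supported sizes otherwise.
    """
    if requested_points not in LEBEDEV_SIZES:
        raise ValueError(
            f"unsupported Lebedev size {requested_points}; "
            f"supported sizes: {sorted(LEBEDEV_SIZES)}"
        )
    order = LEBEDEV_SIZES[requested_points]
    pts, wts = lebedev_rule(order)
    pts = np.ascontiguousarray(pts.T)  # (N, 3)
    wts = np.asarray(wts) / (4.0 * np.pi)
    if len(wts) != requested_points:  # pragma: no cover - sanity guard
        raise RuntimeError("scipy returned an unexpected Lebedev rule size")
    pts.setflags(write=False)
    wts.setflags(write=False)
    return LebedevGrid(order=order, points=pts, weights=wts)


def sph_harm_matrix(basis: HarmonicBasis, directions: np.ndarray) -> np.ndarray:
    """Real orthonormal Y_lm at many unit vectors: shape (n_dir, (L+1)²).

    Built from the complex harmonics of :func:`scipy.special.sph_harm_y`
    (recurrence-based associated Legendre evaluation) via the standard
    real combinations  Y_{l,0} = Y_l^0,
    Y_{l,m>0} = √2 (-1)^m Re Y_l^m,  Y_{l,m<0} = √2 (-1)^m Im Y_l^|m|.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    x, y, z = directions[:, 0], directions[:, 1], directions[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    L = basis.L_max
    out = np.empty((len(directions), basis.n_funcs))
    for l in range(L + 1):
        out[:, l * (l + 1)] = sph_harm_y(l, 0, theta, phi).real
        for m in range(1, l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            s = np.sqrt(2.0) * (-1.0) ** m
            out[:, l * (l + 1) + m] = s * ylm.real
            out[:, l * (l + 1) - m] = s * ylm.imag
    return out


def eval_real_sph_harm(basis: HarmonicBasis, direction: np.ndarray) -> np.ndarray:
    """Evaluate all Y_lm up to L_max at one unit vector.

    The direction must be normalized: ``|direction| = 1`` within 1e-9.
    """
    direction = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(direction))
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"direction must be a unit vector; got norm {norm!r}")
    return sph_harm_matrix(basis, direction[None, :])[0]
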