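"""Adaptive optimization and polynomial fitting of the boundary potential.

The density-flattening loop divides the sphere into constant-width radial
shells and, at fixed intervals, adds a tiny repulsive (overdense) or
attractive (underdense) energy increment to each shell, damping density
fluctuations over time.  The converged tabulated profile — truncated where
it falls below a threshold — is fitted by polynomials of degree 0..12 with
ridge regression, the shrinkage of each degree tuned by a (λ, μ)
evolutionary strategy on cross-validated RMSE, and the degree selected
from the train/test learning curves.
"""

from dataclasses import dataclass, field as dfield

import numpy as np

from .forcefield import MeanFieldPotential

__all__ = [
    "ShellProfile", "FitConfig", "EAParams", "TabulatedMeanField",
    "update_shell_potential", "optimize_boundary_potential",
    "ridge_fit", "evolutionary_search", "fit_polynomial",
]


class TabulatedMeanField:
    """Piecewise-linear boundary potential on a grid of boundary distances.

    Used during the adaptive optimization, before the polynomial fit: the
    per-shell corrections are interpolated linearly so molecules feel a
    piecewise-constant radial force.  The grid must be ascending in
    x = R - |r_COM|; values are clamped at the ends.
    """

    def __init__(self, x_grid, values, cutoff_start):
        self.x = np.asarray(x_grid, dtype=float)
        self.v = np.asarray(values, dtype=float)
        self.cutoff_start = cutoff_start
        self._slopes = np.diff(self.v) / np.diff(self.x)

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.x, self.v)

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(self.x, x) - 1, 0, len(self._slopes) - 1)
        inside = (x > self.x[0]) & (x < self.x[-1])
        return np.where(inside, self._slopes[idx], 0.0)


@dataclass
class ShellProfile:
    """Constant-width radial shells with a tabulated correction energy."""

    radius: float
    n_shells: int = 80
    target_density: float = None          # same units as the samples
    correction: np.ndarray = None         # kJ/mol per shell

    def __post_init__(self):
        if self.n_shells < 1 or self.radius <= 0:
            raise ValueError("need a positive radius and at least one shell")
        if self.correction is None:
            self.correction = np.zeros(self.n_shells)
        self.correction = np.asarray(self.correction, dtype=float)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.radius, self.n_shells + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


def update_shell_potential(profile: ShellProfile, density_window,
                           delta=0.01, delta_max=0.05):
    """One adaptive update from a window of per-shell density samples.

    Each shell receives an increment proportional to its mean relative
    deviation from the target (positive = repulsive for overdense shells),
    capped at ``delta_max`` kJ/mol per update.
    """
    dens = np.atleast_2d(np.asarray(density_window, dtype=float))
    if dens.shape[1] != profile.n_shells:
        raise ValueError("density window does not match the shell count")
    mean = dens.mean(axis=0)
    rel_dev = (mean - profile.target_density) / profile.target_density
    incr = np.clip(delta * rel_dev, -delta_max, delta_max)
    profile.correction = profile.correction + incr
    return profile


def optimize_boundary_potential(topo, positions, config, *, cycles=10,
                                steps_per_cycle=50000, n_shells=80,
                                sample_stride=40, delta=1.0, delta_max=0.3,
                                inner_exclude=3.0, wall_margin=0.8):
    """Adaptive density-flattening loop on a live simulation.

    Runs MD in cycles; after each cycle the per-shell mass-density average
    is compared to the global target and the tabulated correction updated.
    Shells inside ``inner_exclude`` (too few molecules for statistics) are
    left at zero; the geometric wall-depletion layer within ``wall_margin``
    of the boundary is pinned to the last optimized shell value rather than
    fitted (a COM can never populate it, so its density is not a target).

    Returns ``(ShellProfile, profile_table)`` where profile_table is the
    (boundary distance, energy) array ready for :func:`fit_polynomial`.
    """
    from .constants import AVOGADRO_VOL
    from .dynamics import Simulation

    radius = config.radius
    profile = ShellProfile(radius=radius, n_shells=n_shells)
    _, mmass = topo.molecule_com(positions)
    profile.target_density = mmass.sum() / (AVOGADRO_VOL
                                            * 4.0 / 3.0 * np.pi * radius**3)
    edges = profile.edges
    centers = profile.centers
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:]**3 - edges[:-1]**3)
    active = (centers > inner_exclude) & (centers < radius - wall_margin)
    sim = Simulation(topo, positions.copy(), config)
    for _ in range(cycles):
        corr = profile.correction.copy()
        if active.any():
            corr[centers >= radius - wall_margin] = corr[active][-1]
        corr[centers <= inner_exclude] = 0.0
        sim.model.meanfield = TabulatedMeanField(
            (radius - centers)[::-1], corr[::-1], radius)
        dens = []
        for istep in range(steps_per_cycle):
            sim.step()
            if istep % sample_stride == 0:
                com, mm = topo.molecule_com(sim.state.positions)
                idx = np.clip(np.searchsorted(
                    edges, np.linalg.norm(com, axis=1), side="right") - 1,
                    0, n_shells - 1)
                dens.append(np.bincount(idx, weights=mm, minlength=n_shells)
                            / (AVOGADRO_VOL * shell_vol))
        mean_dens = np.asarray(dens).mean(axis=0)
        sub = ShellProfile(radius=radius, n_shells=int(active.sum()),
                           target_density=profile.target_density,
                           correction=profile.correction[active])
        update_shell_potential(sub, mean_dens[None, active],
                               delta=delta, delta_max=delta_max)
        profile.correction[active] = sub.correction
    x = (radius - centers[active])[::-1]
    y = profile.correction[active][::-1]
    return profile, np.column_stack([x, y])


# ---------------------------------------------------------------------------
# ridge regression on a scaled monomial basis

def _design(x: np.ndarray, degree: int, x_scale: float) -> np.ndarray:
    u = np.asarray(x, dtype=float) / x_scale
    return np.vander(u, degree + 1, increasing=True)


def ridge_fit(x, y, degree, lam, x_scale=None):
    """Ridge polynomial fit; returns coefficients in the original x units.

    λ = 0 reduces to ordinary least squares.  Internally the abscissa is
    scaled to order one so the shrinkage acts evenly across degrees; the
    monomial coefficients are rescaled back exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_scale is None:
        x_scale = max(np.abs(x).max(), 1.0)
    X = _design(x, degree, x_scale)
    if lam == 0.0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        # augmented least squares: avoids squaring the condition number
        # that the normal equations would incur at high degree
        n = X.shape[1]
        Xa = np.vstack([X, np.sqrt(lam) * np.eye(n)])
        ya = np.concatenate([y, np.zeros(n)])
        beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    return beta / x_scale ** np.arange(degree + 1)


# ---------------------------------------------------------------------------
# (λ, μ) evolutionary search of the shrinkage

@dataclass
class EAParams:
    population: int = 100          # children evaluated per iteration
    parents: int = 25              # truncation-selected survivors
    mutation_parent: float = 0.3
    mutation_child: float = 0.5
    crossover: float = 0.5
    iterations: int = 500
    sigma_anneal: float = 0.99

    def __post_init__(self):
        for p in (self.mutation_parent, self.mutation_child, self.crossover):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")
        if self.population <= 1:
            raise ValueError("population must exceed 1")


def evolutionary_search(objective, bounds, ea: EAParams, rng):
    """Minimize a scalar objective over [lo, hi] with a (λ, μ)-ES.

    Genes live in log10 space of the (positive) shrinkage.  Children are
    produced by arithmetic crossover and Gaussian mutation (annealed σ);
    comma selection keeps the best ``parents`` children; the incumbent best
    ever seen is returned.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be positive and increasing")
    llo, lhi = np.log10(lo), np.log10(hi)
    span = lhi - llo
    pop = rng.uniform(llo, lhi, size=ea.population)
    sigma = 0.2 * span
    best_x, best_f = None, np.inf
    fitness = np.array([objective(10.0 ** g) for g in pop])
    i = int(np.argmin(fitness))
    best_x, best_f = pop[i], fitness[i]
    for _ in range(ea.iterations):
        order = np.argsort(fitness, kind="stable")
        parents = pop[order[:ea.parents]]
        mut = rng.random(ea.parents) < ea.mutation_parent
        parents = parents + mut * rng.standard_normal(ea.parents) * sigma
        i1 = rng.integers(0, ea.parents, size=ea.population)
        i2 = rng.integers(0, ea.parents, size=ea.population)
        mix = rng.random(ea.population)
        cross = rng.random(ea.population) < ea.crossover
        children = np.where(cross,
                            mix * parents[i1] + (1.0 - mix) * parents[i2],
                            parents[i1])
        mut = rng.random(ea.population) < ea.mutation_child
        children = children + mut * rng.standard_normal(ea.population) * sigma
        children = np.clip(children, llo, lhi)
        fitness = np.array([objective(10.0 ** g) for g in children])
        pop = children
        i = int(np.argmin(fitness))
        if fitness[i] < best_f:
            best_x, best_f = pop[i], fitness[i]
        sigma *= ea.sigma_anneal
    return 10.0 ** best_x


# ---------------------------------------------------------------------------
# degree selection from learning curves

@dataclass
class FitConfig:
    degrees: tuple = tuple(range(13))
    lambda_bounds: tuple = (1e-10, 1e2)
    ea: EAParams = dfield(default_factory=EAParams)
    truncation_threshold: float = 0.1   # kJ/mol
    cutoff_start: float = None          # Å; inferred from the data if None


def fit_polynomial(x, y, config: FitConfig, rng):
    """Ridge + EA fit over the degree grid; returns the selected potential.

    The profile should already be truncated at the threshold; points are
    split into equal-size train/test subsets by alternating index (a
    deterministic 2-fold style split).  For each degree the shrinkage is
    optimized by the evolutionary search on the held-out-half RMSE — the
    same learning-curve objective that selects the degree — so the chosen
    shrinkage is never worse than any single λ on those curves.  The
    returned degree has the lowest test RMSE (ties: highest test R², then
    lowest degree).  Returns ``(MeanFieldPotential, learning_curves)``.
    """
    import pandas as pd
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    train, test = np.arange(0, len(x), 2), np.arange(1, len(x), 2)
    x_scale = max(np.abs(x).max(), 1.0)
    rows = []
    best = None
    def holdout_rmse(degree, lam):
        beta = ridge_fit(x[train], y[train], degree, lam, x_scale)
        pred = np.polynomial.polynomial.polyval(x[test], beta)
        return float(np.sqrt(np.mean((pred - y[test]) ** 2)))

    for degree in config.degrees:
        if len(train) < degree + 1:
            continue
        lam = evolutionary_search(
            lambda l: holdout_rmse(degree, l),
            config.lambda_bounds, config.ea, rng)
        beta = ridge_fit(x[train], y[train], degree, lam, x_scale)
        pred = np.polynomial.polynomial.polyval(x[test], beta)
        resid = pred - y[test]
        rmse = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        pred_tr = np.polynomial.polynomial.polyval(x[train], beta)
        rmse_tr = float(np.sqrt(np.mean((pred_tr - y[train]) ** 2)))
        rows.append(dict(degree=degree, shrinkage=lam, rmse_train=rmse_tr,
                         rmse_test=rmse, r2_test=r2))
        key = (rmse, -r2, degree)
        if best is None or key < best[0]:
            best = (key, beta)
    if best is None:
        raise ValueError("not enough points for any requested degree")
    curves = pd.DataFrame(rows)
    cutoff = config.cutoff_start if config.cutoff_start is not None \
        else float(x.max())
    return MeanFieldPotential(best[1], cutoff_start=cutoff), curves
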