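"""Trajectory mining: feature space → PCA → PAM → validated k → GRASP.

The feature space holds the first and second neighbor distances from
chosen solute sites to chosen solvent atom types.  Frames are clustered by
Partitioning Around Medoids; the cluster count is chosen by a consensus of
Silhouette, Dunn, Calinski–Harabasz and a WSS elbow.  Representative
frames are then drawn per cluster — budget proportional to cluster size —
by a greedy randomized adaptive search procedure (GRASP) maximizing a
density-weighted total dissimilarity, so both dense basins and sparse
fringes of each cluster are covered.
"""

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score, silhouette_score

__all__ = [
    "FeatureMatrix", "Projection", "ClusterModel", "GRASPConfig",
    "SelectionResult", "build_features", "project", "pam_cluster",
    "select_k", "knn_density_weights", "grasp_select", "largest_remainder",
    "allocate_and_select",
]


@dataclass
class FeatureMatrix:
    values: np.ndarray                   # (n_frames, n_features), Å
    frame_indices: np.ndarray
    feature_names: list
    stride_ps: float = 10.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class Projection:
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    dimension: int


@dataclass
class ClusterModel:
    k: int
    medoids: np.ndarray                  # indices into the point set
    labels: np.ndarray
    scores: dict = dfield(default_factory=dict)


@dataclass
class GRASPConfig:
    alpha: float = 0.1                   # 0 = greedy, 1 = random
    neighborhood_fraction: float = 0.05
    restarts: int = 100
    knn: int = 10                        # for the density weights
    literal_rcl: bool = False            # keep the low-dissimilarity band

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class SelectionResult:
    labels: np.ndarray
    medoids: np.ndarray
    scores: dict
    selected: np.ndarray                 # selected frame indices, sorted
    per_cluster: list                    # list of index arrays


# ---------------------------------------------------------------------------
# feature construction

def build_features(frames, site_indices, site_names, solvent_groups,
                   stride: int = 1, stride_ps: float = 10.0) -> FeatureMatrix:
    """First and second neighbor distances from sites to solvent atom types.

    ``solvent_groups`` maps a type name to an atom index array; every
    (site, type) pair contributes its two smallest distances, giving
    len(sites) × len(groups) × 2 features.
    """
    for name, idx in solvent_groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"need at least 2 solvent atoms of type {name!r}")
    names = []
    for sname in site_names:
        for gname in solvent_groups:
            names += [f"{sname}-{gname}-1", f"{sname}-{gname}-2"]
    rows = []
    used = []
    for iframe, (time, radius, pos) in enumerate(frames):
        if iframe % stride:
            continue
        used.append(iframe)
        row = []
        for s in site_indices:
            for gname, idx in solvent_groups.items():
                d = np.linalg.norm(pos[np.asarray(idx)] - pos[s], axis=1)
                two = np.partition(d, 1)[:2]
                row += [min(two), max(two)]
        rows.append(row)
    return FeatureMatrix(values=np.asarray(rows),
                         frame_indices=np.asarray(used),
                         feature_names=names, stride_ps=stride_ps)


# ---------------------------------------------------------------------------
# projection

def project(features: FeatureMatrix, threshold: float = 0.9):
    """Centered (unscaled) PCA keeping the smallest dimension above threshold.

    Returns ``(Projection, projected coordinates)``.
    """
    X = features.values
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("feature matrix has zero variance")
    pca = PCA()
    coords = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    d = int(np.searchsorted(np.cumsum(ratios), threshold) + 1)
    d = min(d, len(ratios))
    proj = Projection(components=pca.components_[:d],
                      explained_variance_ratio=ratios, dimension=d)
    return proj, coords[:, :d]


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)

def pam_cluster(points, k, rng=None, max_swaps=200) -> ClusterModel:
    """Partitioning Around Medoids on Euclidean distances.

    Deterministic: BUILD greedily seeds the medoids, SWAP applies the best
    improving (medoid, non-medoid) exchange until none improves.  Ties are
    broken toward the lowest index.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    D = squareform(pdist(points))
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gain = np.sum(np.maximum(dmin[None, :] - D, 0.0), axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = sorted(medoids)
    # SWAP: best improving exchange, evaluated via nearest/second-nearest
    # medoid distances so each sweep costs O(k·n²)
    for _ in range(max_swaps):
        Dm = D[:, medoids]
        order = np.argsort(Dm, axis=1, kind="stable")
        d1 = Dm[np.arange(n), order[:, 0]]
        d2 = Dm[np.arange(n), order[:, 1]]
        nearest = order[:, 0]
        cost = d1.sum()
        best = (0.0, None)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        for mi in range(len(medoids)):
            alt = np.where(nearest == mi, d2, d1)
            costs = np.minimum(alt[:, None], D).sum(axis=0)
            costs[is_medoid] = np.inf
            h = int(np.argmin(costs))
            delta = costs[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    medoids = np.asarray(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return ClusterModel(k=k, medoids=medoids, labels=labels,
                        scores={"WSS": float(np.sum(
                            D[np.arange(n), medoids[labels]] ** 2))})


def dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    ks = np.unique(labels)
    diam = 0.0
    for k in ks:
        sel = labels == k
        if sel.sum() > 1:
            diam = max(diam, float(D[np.ix_(sel, sel)].max()))
    sep = np.inf
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            sep = min(sep, float(D[np.ix_(labels == a, labels == b)].min()))
    return sep / diam if diam > 0 else np.inf


def select_k(points, k_range=range(2, 21), rng=None):
    """Consensus cluster count from SI, DI, pSF and the WSS elbow.

    Each of Silhouette, Dunn and Calinski–Harabasz votes for its argmax;
    the WSS elbow votes for the largest discrete second difference.  The
    returned k has at least three votes; otherwise the most-voted k wins
    (ties toward smaller k) and the result is flagged.
    Returns ``(k, models dict, scores DataFrame, consensus flag)``.
    """
    import pandas as pd
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ValueError("empty k range")
    D = squareform(pdist(points))
    models, rows = {}, []
    for k in ks:
        model = pam_cluster(points, k, rng)
        si = silhouette_score(points, model.labels) \
            if len(np.unique(model.labels)) > 1 else -1.0
        di = dunn_index(D, model.labels)
        psf = calinski_harabasz_score(points, model.labels) \
            if len(np.unique(model.labels)) > 1 else 0.0
        model.scores.update(SI=float(si), DI=float(di), pSF=float(psf))
        models[k] = model
        rows.append(dict(k=k, SI=si, DI=di, pSF=psf, WSS=model.scores["WSS"]))
    table = pd.DataFrame(rows).set_index("k")
    votes = {}
    for crit in ("SI", "DI", "pSF"):
        votes.setdefault(int(table[crit].idxmax()), []).append(crit)
    wss = table["WSS"].to_numpy()
    if len(wss) >= 3:
        elbow = ks[int(np.argmax(wss[:-2] - 2 * wss[1:-1] + wss[2:]) + 1)]
        votes.setdefault(elbow, []).append("WSS")
    best_k = max(votes, key=lambda k: (len(votes[k]), -k))
    consensus = len(votes[best_k]) >= 3
    return best_k, models, table, consensus


# ---------------------------------------------------------------------------
# GRASP

def knn_density_weights(D: np.ndarray, knn: int = 10) -> np.ndarray:
    """w_i ∝ (kNN density)^(-1/2), normalized to mean 1.

    The local density estimate is k / (mean distance to the k nearest
    neighbors); sparse points get larger weights so the selection covers
    low-density regions.
    """
    n = len(D)
    k = min(knn, n - 1)
    if k < 1:
        return np.ones(n)
    nn = np.sort(D, axis=1)[:, 1:k + 1]
    mean_d = np.maximum(nn.mean(axis=1), 1e-12)
    dens = k / mean_d
    w = dens ** -0.5
    return w / w.mean()


def _ds_objective(D, w, members):
    sel = np.asarray(sorted(members))
    if len(sel) < 2:
        return 0.0
    sub = D[np.ix_(sel, sel)]
    ww = np.outer(w[sel], w[sel])
    return float(np.sum(np.triu(sub * ww, k=1)))


def grasp_select(points, budget, config: GRASPConfig, rng,
                 weights=None, must_include=None):
    """GRASP maximization of DS(F) = Σ_{i<j∈F} w_i w_j d(i, j).

    Construction samples from the restricted candidate list — by default
    the top-α band of incremental dissimilarity (maximization convention;
    set ``literal_rcl`` for the low band) — and local search swaps each
    member against its nearest neighbors (up to ``neighborhood_fraction``
    of the set).  Best of ``restarts`` runs; deterministic under a seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if budget > n:
        raise ValueError("budget exceeds the cluster size")
    if budget == 0:
        return np.array([], dtype=int)
    D = squareform(pdist(points))
    w = knn_density_weights(D, config.knn) if weights is None \
        else np.asarray(weights, dtype=float)
    must = set(int(i) for i in (must_include or []))
    if budget == n:
        return np.arange(n)
    wD = w[:, None] * w[None, :] * D
    n_neigh = max(1, int(np.ceil(config.neighborhood_fraction * n)))
    neigh_order = np.argsort(D, axis=1, kind="stable")
    best_set, best_val = None, -np.inf
    for _ in range(config.restarts):
        sel = set(must)
        if not sel:
            # seed with a weighted-dissimilarity RCL over all points
            total = wD.sum(axis=1)
            sel.add(_rcl_pick(total, config, rng, exclude=()))
        while len(sel) < budget:
            sel_idx = np.fromiter(sel, int)
            incr = wD[:, sel_idx].sum(axis=1)
            pick = _rcl_pick(incr, config, rng, exclude=sel)
            sel.add(pick)
        # local search: swap members with nearby non-members
        improved = True
        val = _ds_objective(D, w, sel)
        while improved:
            improved = False
            for member in sorted(sel):
                others = np.fromiter(sel - {member}, int)
                base = wD[others][:, others]
                cur = val
                for cand in neigh_order[member, 1:n_neigh + 1]:
                    if cand in sel or member in must:
                        continue
                    delta = wD[cand, others].sum() - wD[member, others].sum()
                    if val + delta > cur + 1e-12:
                        cur = val + delta
                        best_swap = int(cand)
                if cur > val + 1e-12:
                    sel.remove(member)
                    sel.add(best_swap)
                    val = cur
                    improved = True
        if val > best_val:
            best_val, best_set = val, sel
    return np.asarray(sorted(best_set))


def _rcl_pick(scores, config, rng, exclude):
    mask = np.ones(len(scores), dtype=bool)
    for e in exclude:
        mask[e] = False
    idx = np.flatnonzero(mask)
    vals = scores[idx]
    lo, hi = vals.min(), vals.max()
    if config.literal_rcl:
        band = idx[vals <= lo + config.alpha * (hi - lo) + 1e-15]
    else:
        band = idx[vals >= hi - config.alpha * (hi - lo) - 1e-15]
    return int(band[rng.integers(0, len(band))])


def largest_remainder(sizes, total: int) -> np.ndarray:
    """Proportional allocation of ``total`` over ``sizes`` (largest remainder)."""
    sizes = np.asarray(sizes, dtype=float)
    quota = total * sizes / sizes.sum()
    alloc = np.floor(quota).astype(int)
    rem = quota - alloc
    short = total - alloc.sum()
    for i in np.argsort(-rem, kind="stable")[:short]:
        alloc[i] += 1
    return alloc


def allocate_and_select(model: ClusterModel, points, total_frames: int,
                        config: GRASPConfig, rng) -> SelectionResult:
    """Per-cluster GRASP with proportional budgets; medoids always included."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if total_frames > len(points):
        raise ValueError("total_frames exceeds the number of frames")
    sizes = np.bincount(model.labels, minlength=model.k)
    budgets = largest_remainder(sizes, total_frames)
    per_cluster, selected = [], []
    for c in range(model.k):
        members = np.flatnonzero(model.labels == c)
        budget = int(budgets[c])
        if budget == 0:
            per_cluster.append(np.array([], dtype=int))
            continue
        local_medoid = int(np.flatnonzero(members == model.medoids[c])[0])
        picks = grasp_select(points[members], budget, config, rng,
                             must_include=[local_medoid])
        chosen = members[picks]
        per_cluster.append(chosen)
        selected.append(chosen)
    selected = np.sort(np.concatenate(selected)) if selected \
        else np.array([], dtype=int)
    return SelectionResult(labels=model.labels, medoids=model.medoids,
                           scores=model.scores, selected=selected,
                           per_cluster=per_cluster)
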