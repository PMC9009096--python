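"""Feature space, PCA threshold, PAM, k consensus, GRASP selection."""

import itertools

import numpy as np
import pytest

from npbcmd.fixtures import synth_feature_trajectory
from npbcmd.snapshot_selection import (FeatureMatrix, GRASPConfig,
                                       allocate_and_select, build_features,
                                       grasp_select, knn_density_weights,
                                       largest_remainder, pam_cluster,
                                       project, select_k)


def blobs(rng, means, n_per, sigma=1.0):
    means = np.asarray(means, dtype=float)
    pts = np.concatenate([
        m + sigma * rng.standard_normal((n_per, means.shape[1]))
        for m in means])
    labels = np.repeat(np.arange(len(means)), n_per)
    return pts, labels


class TestBuildFeatures:
    def frames_with_solvent(self, solvent_positions):
        pos = np.vstack([[[0.0, 0.0, 0.0]], solvent_positions])
        return [(0.0, 10.0, pos)]

    def test_hand_placed_distances(self):
        frames = self.frames_with_solvent([[2.0, 0, 0], [0, 3.5, 0],
                                           [0, 0, 7.0]])
        fm = build_features(frames, site_indices=[0], site_names=["N"],
                            solvent_groups={"O": np.array([1, 2, 3])})
        assert fm.values[0].tolist() == [2.0, 3.5]
        assert fm.feature_names == ["N-O-1", "N-O-2"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        solvent = rng.uniform(-5, 5, (6, 3))
        f1 = build_features(self.frames_with_solvent(solvent),
                            [0], ["N"], {"O": np.arange(1, 7)})
        perm = rng.permutation(6)
        f2 = build_features(self.frames_with_solvent(solvent[perm]),
                            [0], ["N"], {"O": np.arange(1, 7)})
        assert np.allclose(f1.values, f2.values)

    def test_against_brute_force_sort(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            solvent = rng.uniform(-6, 6, (9, 3))
            fm = build_features(self.frames_with_solvent(solvent),
                                [0], ["N"], {"O": np.arange(1, 10)})
            d = np.sort(np.linalg.norm(solvent, axis=1))
            assert np.allclose(fm.values[0], d[:2])

    def test_too_few_solvent_atoms(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_features(self.frames_with_solvent([[1.0, 0, 0]]),
                           [0], ["N"], {"O": np.array([1])})


class TestProjection:
    def make_fm(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(values=values,
                             frame_indices=np.arange(len(values)),
                             feature_names=[f"f{i}" for i in
                                            range(values.shape[1])])

    def test_planar_data_gives_two_components(self):
        rng = np.random.default_rng(2)
        basis = rng.standard_normal((2, 5))
        coords2 = rng.standard_normal((200, 2))
        proj, coords = project(self.make_fm(coords2 @ basis))
        assert proj.dimension == 2
        assert np.cumsum(proj.explained_variance_ratio)[1] == \
            pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_needs_all_dimensions(self):
        rng = np.random.default_rng(3)
        proj, _ = project(self.make_fm(rng.standard_normal((4000, 4))))
        assert proj.dimension == 4

    def test_single_dominant_direction(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((500, 1)) * 30.0
        noise = rng.standard_normal((500, 3)) * 0.1
        proj, coords = project(self.make_fm(np.hstack([x, noise])))
        assert proj.dimension == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            project(self.make_fm(np.ones((10, 3))))


class TestPAM:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(5)
        pts, truth = blobs(rng, [[0, 0], [12, 0]], 100)
        model = pam_cluster(pts, 2)
        agree = max(np.mean(model.labels == truth),
                    np.mean(model.labels == 1 - truth))
        assert agree >= 0.99
        assert sorted(model.labels[model.medoids]) == [0, 1]

    def test_k_equals_n(self):
        pts = np.arange(6, dtype=float)[:, None] * 3.0
        model = pam_cluster(pts, 6)
        assert set(model.medoids) == set(range(6))
        assert model.scores["WSS"] == 0.0

    def test_two_pairs_match_exhaustive_enumeration(self):
        pts = np.array([[0.0, 0], [1.0, 0], [10.0, 0], [11.0, 0]])
        model = pam_cluster(pts, 2)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        best_cost, best_pair = np.inf, None
        for pair in itertools.combinations(range(4), 2):
            cost = d[:, pair].min(axis=1).sum()
            if cost < best_cost:
                best_cost, best_pair = cost, pair
        assert d[:, model.medoids].min(axis=1).sum() == \
            pytest.approx(best_cost)
        # one medoid per pair (several medoid choices tie at the optimum)
        assert (model.medoids < 2).sum() == 1

    def test_medoids_belong_to_their_clusters(self):
        rng = np.random.default_rng(6)
        pts, _ = blobs(rng, [[0, 0], [6, 0], [0, 6]], 40)
        model = pam_cluster(pts, 3)
        for c, m in enumerate(model.medoids):
            assert model.labels[m] == c


class TestSelectK:
    def test_three_separated_blobs(self):
        rng = np.random.default_rng(7)
        pts, _ = blobs(rng, [[0, 0], [15, 0], [0, 15]], 60)
        k, models, table, consensus = select_k(pts, range(2, 9))
        assert k == 3 and consensus

    def test_two_blobs_all_three_scores_agree(self):
        rng = np.random.default_rng(8)
        pts, _ = blobs(rng, [[0, 0, 0], [14, 0, 0]], 80)
        k, models, table, consensus = select_k(pts, range(2, 8))
        assert k == 2 and consensus
        assert table["SI"].idxmax() == 2
        assert table["DI"].idxmax() == 2
        assert table["pSF"].idxmax() == 2

    def test_structureless_data_flags_no_consensus(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((150, 2))
        k, models, table, consensus = select_k(pts, range(2, 8))
        assert table["SI"].max() < 0.5  # no real cluster structure


class TestGRASP:
    def test_alpha_zero_budget_two_is_farthest_pair(self):
        pts = np.array([[0.0, 0], [1.0, 0], [2.5, 0.5], [4.0, 1],
                        [9.0, 0]])
        w = np.ones(5)
        config = GRASPConfig(alpha=0.0, restarts=5)
        sel = grasp_select(pts, 2, config, np.random.default_rng(0),
                           weights=w)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        best = max(itertools.combinations(range(5), 2),
                   key=lambda p: d[p[0], p[1]])
        assert set(sel) == set(best)

    def test_full_budget_returns_everything(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((7, 2))
        sel = grasp_select(pts, 7, GRASPConfig(), rng)
        assert np.array_equal(sel, np.arange(7))

    def test_budget_zero_empty(self):
        sel = grasp_select(np.zeros((4, 2)), 0, GRASPConfig(),
                           np.random.default_rng(2))
        assert len(sel) == 0

    def test_colinear_points_match_enumeration(self):
        pts = np.arange(7, dtype=float)[:, None]
        w = np.ones(7)
        config = GRASPConfig(alpha=0.1, restarts=50,
                             neighborhood_fraction=0.5)
        sel = grasp_select(pts, 3, config, np.random.default_rng(3),
                           weights=w)
        d = np.abs(pts - pts.T)
        best_val = max(
            sum(d[i, j] for i, j in itertools.combinations(c, 2))
            for c in itertools.combinations(range(7), 3))
        val = sum(d[i, j] for i, j in itertools.combinations(sel, 2))
        assert val == pytest.approx(best_val)

    def test_never_worse_than_pure_greedy(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            pts = rng.standard_normal((30, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            w = knn_density_weights(d)

            def objective(sel):
                return sum(w[i] * w[j] * d[i, j]
                           for i, j in itertools.combinations(sel, 2))

            greedy = grasp_select(pts, 4, GRASPConfig(alpha=0.0, restarts=1),
                                  np.random.default_rng(seed))
            full = grasp_select(pts, 4, GRASPConfig(alpha=0.1, restarts=20),
                                np.random.default_rng(seed))
            assert objective(full) >= objective(greedy) - 1e-12

    def test_brute_force_optimality_rate(self):
        """≥95% of small random instances reach the enumerated optimum."""
        hits = 0
        n_instances = 40
        for seed in range(n_instances):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(8, 16))
            pts = rng.standard_normal((n, 2))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            w = knn_density_weights(d)
            sel = grasp_select(pts, 3, GRASPConfig(alpha=0.1, restarts=100,
                                                   neighborhood_fraction=0.3),
                               rng, weights=w)

            def val(c):
                return sum(w[i] * w[j] * d[i, j]
                           for i, j in itertools.combinations(c, 2))

            best = max(val(c) for c in itertools.combinations(range(n), 3))
            if val(sel) >= best - 1e-9:
                hits += 1
        assert hits / n_instances >= 0.95

    def test_deterministic_under_seed(self):
        rng_pts = np.random.default_rng(5)
        pts = rng_pts.standard_normal((25, 2))
        a = grasp_select(pts, 5, GRASPConfig(), np.random.default_rng(9))
        b = grasp_select(pts, 5, GRASPConfig(), np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestAllocation:
    def test_printed_two_cluster_split(self):
        assert largest_remainder([707, 548], 64).tolist() == [36, 28]

    def test_printed_three_cluster_split(self):
        assert largest_remainder([173, 425, 343], 51).tolist() == [9, 23, 19]

    def test_single_cluster_takes_everything(self):
        assert largest_remainder([100], 17).tolist() == [17]

    def test_allocate_and_select_includes_medoids(self):
        rng = np.random.default_rng(10)
        fm, labels = synth_feature_trajectory(
            [(0.48, [0.0, 0.0], 0.5), (0.52, [8.0, 0.0], 0.5)], 300, seed=11)
        model = pam_cluster(fm.values, 2)
        result = allocate_and_select(model, fm.values, 30, GRASPConfig(), rng)
        assert len(result.selected) == 30
        for m in model.medoids:
            assert m in result.selected
        sizes = np.bincount(model.labels)
        budgets = largest_remainder(sizes, 30)
        for c, chosen in enumerate(result.per_cluster):
            assert len(chosen) == budgets[c]
            assert np.all(model.labels[chosen] == c)


class TestPipelineDeterminism:
    def test_end_to_end_reproducible(self):
        fm, labels = synth_feature_trajectory(
            [(0.5, [0, 0, 0], 1.0), (0.5, [10, 0, 0], 1.0)], 200, seed=12)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(13)
            proj, coords = project(fm)
            k, models, table, consensus = select_k(coords, range(2, 6))
            res = allocate_and_select(models[k], coords, 20,
                                      GRASPConfig(), rng)
            out.append(res.selected)
        assert np.array_equal(out[0], out[1])
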