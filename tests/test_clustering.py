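"""Seeded k-means, silhouette validation, seed rules and the split test."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mldcyto import (Centroid, PipelineConfig, kmeans_assign, silhouette,
                     update_seeds)
from mldcyto.clustering import (ClusterState, auto_seed,
                                mean_pairwise_separation, run_split_tests,
                                split_cluster, wcss)


def brute_force_lloyd(elements, seeds, max_iter=100, tol=0.5):
    """Independent plain-Python Lloyd iteration (ties -> lowest seed index)."""
    centres = [np.array(s, dtype=float) for s in seeds]
    for _ in range(max_iter):
        groups = [[] for _ in centres]
        for e in elements:
            dists = [np.linalg.norm(e - c) for c in centres]
            groups[int(np.argmin(dists))].append(e)
        new = [np.mean(g, axis=0) if g else c
               for g, c in zip(groups, centres)]
        shift = max(np.linalg.norm(a - b) for a, b in zip(new, centres))
        centres = new
        if shift <= tol:
            break
    labels = [int(np.argmin([np.linalg.norm(e - c) for c in centres]))
              for e in elements]
    return centres, labels


def brute_force_silhouette(elements, labels):
    """Direct per-element silhouette from raw pairwise distances."""
    n = len(elements)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(elements[i] - elements[j]) for j in own])
        bs = []
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            bs.append(np.mean([np.linalg.norm(elements[i] - elements[j])
                               for j in other]))
        b = min(bs)
        scores.append((b - a) / max(a, b))
    return np.array(scores)


class TestKMeans:
    def test_coincident_elements_single_seed(self):
        elements = np.tile([5.0, 7.0], (10, 1))
        state = kmeans_assign(elements, [Centroid(0, 50.0, 50.0)])
        assert len(state.centroids) == 1
        assert state.centroids[0].x == 5.0 and state.centroids[0].y == 7.0

    def test_two_blobs_recover_means(self, rng):
        a = rng.normal([0, 0], 2, (10, 2))
        b = rng.normal([100, 0], 2, (10, 2))
        elements = np.vstack([a, b])
        state = kmeans_assign(elements, [Centroid(0, 5, 5), Centroid(1, 95, -5)])
        assert np.allclose([state.centroids[0].x, state.centroids[0].y],
                           a.mean(axis=0), atol=1e-9)
        assert np.allclose([state.centroids[1].x, state.centroids[1].y],
                           b.mean(axis=0), atol=1e-9)

    def test_converged_seeds_are_fixed_point(self, rng):
        elements = rng.normal(0, 5, (30, 2))
        s1 = kmeans_assign(elements, [Centroid(0, -1, 0), Centroid(1, 1, 0)])
        seeds = [Centroid(c.id, c.x, c.y) for c in s1.centroids]
        s2 = kmeans_assign(elements, seeds)
        for c1, c2 in zip(s1.centroids, s2.centroids):
            assert (c1.x, c1.y) == (c2.x, c2.y)

    def test_no_elements_rejected(self):
        with pytest.raises(ValueError):
            kmeans_assign(np.zeros((0, 2)), [Centroid(0, 0, 0)])

    def test_degenerate_seeds_collapse_with_survivors(self):
        elements = np.tile([1.0, 1.0], (5, 1))
        state = kmeans_assign(elements, [Centroid(0, 1, 1), Centroid(1, 2, 2)])
        assert len(state.centroids) == 1

    def test_objective_non_increasing_over_iterations(self, rng):
        """The within-cluster sum of squares never rises across Lloyd steps."""
        elements = rng.uniform(0, 100, (60, 2))
        seeds = [(10.0, 10.0), (50.0, 50.0), (90.0, 20.0)]
        centres = [np.array(s) for s in seeds]
        prev_obj = np.inf
        for _ in range(20):
            d = cdist(elements, np.array(centres))
            labels = np.argmin(d, axis=1)
            obj = sum(np.sum((elements[labels == k] - centres[k]) ** 2)
                      for k in range(len(centres)))
            assert obj <= prev_obj + 1e-9
            prev_obj = obj
            centres = [elements[labels == k].mean(axis=0)
                       if (labels == k).any() else centres[k]
                       for k in range(len(centres))]

    @pytest.mark.parametrize("case", range(25))
    def test_matches_brute_force_lloyd(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(5, 50))
        k = int(rng.integers(1, 5))
        elements = rng.uniform(0, 100, (n, 2))
        seed_xy = rng.uniform(0, 100, (k, 2))
        state = kmeans_assign(elements, [Centroid(i, *s) for i, s in
                                         enumerate(seed_xy)], tol_px=1e-9)
        centres, labels = brute_force_lloyd(elements, seed_xy, tol=1e-9)
        got = {(round(c.x, 6), round(c.y, 6)) for c in state.centroids}
        expect = {(round(float(c[0]), 6), round(float(c[1]), 6))
                  for c in centres if any(np.array_equal(c, centres[l])
                                          for l in labels)}
        assert got == expect


class TestSilhouette:
    def test_hand_computed_four_points(self):
        elements = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        scores, mean = silhouette(elements, labels)
        b = (10 + np.sqrt(101)) / 2
        expect = (b - 1) / b
        assert np.allclose(scores, expect)
        assert mean == pytest.approx(expect)
        assert mean == pytest.approx(0.900, abs=5e-3)

    def test_well_separated_tight_clusters_near_one(self, rng):
        a = rng.normal([0, 0], 0.01, (20, 2))
        b = rng.normal([1000, 0], 0.01, (20, 2))
        _, mean = silhouette(np.vstack([a, b]), np.repeat([0, 1], 20))
        assert mean > 0.999

    def test_interleaved_split_of_one_blob_scores_nonpositive(self, rng):
        elements = rng.normal(0, 1, (40, 2))
        labels = np.tile([0, 1], 20)
        scores, mean = silhouette(elements, labels)
        oracle = brute_force_silhouette(elements, labels)
        assert np.allclose(scores, oracle)
        assert mean <= 0.05  # random interleave cannot look well-clustered

    def test_single_cluster_convention(self, rng):
        _, mean = silhouette(rng.normal(0, 1, (10, 2)), np.zeros(10))
        assert mean == 0.0

    def test_singleton_member_scores_zero(self):
        elements = np.array([[0, 0], [1, 0], [50, 0]], dtype=float)
        scores, _ = silhouette(elements, np.array([0, 0, 1]))
        assert scores[2] == 0.0

    @pytest.mark.parametrize("case", range(25))
    def test_matches_brute_force(self, case):
        rng = np.random.default_rng(2000 + case)
        n = int(rng.integers(4, 50))
        k = int(rng.integers(2, 5))
        elements = rng.uniform(0, 50, (n, 2))
        labels = rng.integers(0, k, n)
        scores, mean = silhouette(elements, labels)
        oracle = brute_force_silhouette(elements, labels)
        assert np.allclose(scores, oracle)
        assert mean == pytest.approx(oracle.mean())


def _state_from(elements, centroid_xy, labels, pixel_size=0.25, frame=0):
    elements = np.asarray(elements, dtype=float)
    cents = [Centroid(i, x, y, frame) for i, (x, y) in enumerate(centroid_xy)]
    st = ClusterState(frame, elements, cents, np.asarray(labels), pixel_size)
    from mldcyto.clustering import _compute_metrics
    _compute_metrics(st)
    st.silhouette_mean = silhouette(elements, np.asarray(labels))[1]
    return st


class TestSeedRules:
    def test_far_element_spawns_seed(self, id_counter):
        prev = _state_from([[0.0, 0.0]], [(0.0, 0.0)], [0])
        elements = np.array([[0.0, 0.0], [121.0, 0.0]])
        seeds = update_seeds(prev, elements, spawn_px=120, removal_px=50,
                             id_counter=itertools.count(10))
        assert len(seeds) == 2
        assert (seeds[1].x, seeds[1].y) == (121.0, 0.0)

    def test_element_at_120px_does_not_spawn(self):
        prev = _state_from([[0.0, 0.0]], [(0.0, 0.0)], [0])
        elements = np.array([[0.0, 0.0], [120.0, 0.0]])
        seeds = update_seeds(prev, elements, 120, 50, itertools.count(10))
        assert len(seeds) == 1

    def test_orphan_seed_removed(self):
        prev = _state_from([[0.0, 0.0]], [(0.0, 0.0), (200.0, 0.0)], [0])
        elements = np.array([[51.0, 0.0]])
        # centroid at origin: nearest element 51 px away -> removed;
        # centroid at 200: nearest element 149 px away -> removed too
        seeds = update_seeds(prev, elements, 120, 50, itertools.count(10))
        assert [s.id for s in seeds] == []

    def test_seed_within_50px_kept(self):
        prev = _state_from([[0.0, 0.0]], [(0.0, 0.0)], [0])
        elements = np.array([[50.0, 0.0]])
        seeds = update_seeds(prev, elements, 120, 50, itertools.count(10))
        assert [s.id for s in seeds] == [0]

    def test_identical_frame_keeps_seed_set(self, rng):
        elements = rng.uniform(0, 40, (12, 2))
        prev = _state_from(elements, [elements.mean(axis=0)],
                           np.zeros(len(elements), dtype=int))
        seeds = update_seeds(prev, elements, 120, 50, itertools.count(10))
        assert [(s.id, s.x, s.y) for s in seeds] == \
            [(c.id, c.x, c.y) for c in prev.centroids]

    def test_spawned_seed_shields_following_elements(self):
        prev = _state_from([[0.0, 0.0]], [(0.0, 0.0)], [0])
        elements = np.array([[0.0, 0.0], [200.0, 0.0], [210.0, 0.0]])
        seeds = update_seeds(prev, elements, 120, 50, itertools.count(10))
        assert len(seeds) == 2  # second far element is near the new seed

    def test_auto_seed_groups_by_linking_radius(self):
        elements = np.array([[0, 0], [5, 0], [300, 300], [302, 299]],
                            dtype=float)
        seeds = auto_seed(elements, 30.0, itertools.count(0))
        assert len(seeds) == 2


class TestSplit:
    def _bimodal_state(self, rng, sep_um=34.0, pixel_size=0.25):
        """One mis-merged cluster of two sub-blobs plus a distant normal cell."""
        sep_px = sep_um / pixel_size
        a = rng.normal([0, 0], 4, (10, 2))
        b = rng.normal([sep_px, 0], 4, (10, 2))
        other = rng.normal([500, 500], 6, (12, 2))
        elements = np.vstack([a, b, other])
        merged = np.vstack([a, b]).mean(axis=0)
        labels = np.array([0] * 20 + [1] * 12)
        return _state_from(elements, [merged, other.mean(axis=0)], labels,
                           pixel_size)

    def test_bimodal_cluster_splits_to_subblob_means(self, rng, config):
        state = self._bimodal_state(rng)
        assert state.mean_separation_um[0] > config.split_separation_um
        out, accepted = run_split_tests(state, config, itertools.count(100))
        assert len(accepted) == 1
        assert len(out.centroids) == 3
        # the two products sit near the sub-blob means
        sub_means = [state.elements[:10].mean(axis=0),
                     state.elements[10:20].mean(axis=0)]
        prods = [c for c in out.centroids if c.id >= 100]
        for c in prods:
            assert min(np.linalg.norm(c.xy - m) for m in sub_means) < 3.0

    def test_tight_cluster_not_attempted(self, rng, config):
        pts = rng.normal([0, 0], 4, (15, 2))  # ~3 um spread at 0.25 um/px
        other = rng.normal([400, 400], 4, (10, 2))
        state = _state_from(np.vstack([pts, other]),
                            [pts.mean(axis=0), other.mean(axis=0)],
                            [0] * 15 + [1] * 10)
        assert state.mean_separation_um[0] < config.split_separation_um
        out, accepted = run_split_tests(state, config, itertools.count(100))
        assert accepted == []
        assert len(out.centroids) == 2

    def test_elongated_cluster_split_rejected_when_silhouette_worsens(self, config):
        # a uniform line of points ~50 um long (mean pairwise separation
        # ~L/3 = 16.6 um, above the 15 um trigger), but cutting it in half
        # moves each element's nearest-other-cluster distance from the
        # far-away cell to the adjacent half, so the mean silhouette drops
        # and the split must be rejected.
        xs = np.linspace(0, 200, 26)
        line = np.stack([xs, np.zeros_like(xs)], axis=1)
        other = np.stack([np.linspace(2000, 2004, 8), np.zeros(8)], axis=1)
        elements = np.vstack([line, other])
        labels = np.array([0] * len(line) + [1] * len(other))
        state = _state_from(elements, [line.mean(axis=0), other.mean(axis=0)],
                            labels)
        assert state.mean_separation_um[0] > config.split_separation_um
        # independent check of the comparison direction with sklearn
        from sklearn.metrics import silhouette_score
        half = np.array([0] * 13 + [2] * 13 + [1] * 8)
        assert silhouette_score(elements, half) < \
            silhouette_score(elements, labels)
        out, accepted = run_split_tests(state, config, itertools.count(100))
        assert accepted == []
        assert len(out.centroids) == 2

    def test_single_element_cluster_never_split(self, config):
        state = _state_from([[0.0, 0.0], [400.0, 0.0], [404.0, 0.0]],
                            [(0.0, 0.0), (402.0, 0.0)], [0, 1, 1])
        out, ok, ids = split_cluster(state, 0, config, itertools.count(10))
        assert not ok and ids is None

    def test_forced_split_partitions_elements(self, rng, config):
        state = self._bimodal_state(rng, sep_um=8.0)  # below 15 um trigger
        out, ok, (a, b) = split_cluster(state, 0, config,
                                        itertools.count(100), force=True)
        assert ok
        assert out.n_elements[a] + out.n_elements[b] == 20


class TestMetrics:
    def test_mean_pairwise_separation_square(self):
        square = np.array([[0, 0], [40, 0], [0, 40], [40, 40]], dtype=float)
        # 10 um square at 0.25 um/px: (4*10 + 2*10*sqrt(2))/6 um
        expect_um = (4 * 10 + 2 * 10 * np.sqrt(2)) / 6
        assert mean_pairwise_separation(square) * 0.25 == \
            pytest.approx(expect_um)

    def test_partition_property(self, rng):
        elements = rng.uniform(0, 200, (50, 2))
        seeds = [Centroid(i, *xy) for i, xy in
                 enumerate(rng.uniform(0, 200, (4, 2)))]
        state = kmeans_assign(elements, seeds)
        assert sum(state.n_elements.values()) == len(elements)
        assert len(state.assignment) == len(elements)
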