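"""Anchor adequacy metrics, k-means re-estimation, genetic refinement."""

from itertools import product

import numpy as np
import pytest

from fruitfusion.anchors import (DEFAULT_ANCHORS, AnchorSet, aat,
                                 anchor_fitness, bpr, check_anchors,
                                 ga_refine, kmeans_anchors, ratio_metric)


def exhaustive_kmeans_objective(wh, k):
    """Global minimum of the k-means objective by enumerating all
    assignments (normalized (w, h) space, clusters must be non-empty)."""
    scale = wh.max(axis=0)
    X = wh / scale
    best = np.inf
    for assign in product(range(k), repeat=len(X)):
        assign = np.array(assign)
        if len(set(assign.tolist())) < k:
            continue
        sse = 0.0
        for j in range(k):
            members = X[assign == j]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


@pytest.fixture(scope="module")
def clustered_boxes():
    """Box dimensions drawn around three size modes, like fruit labels."""
    r = np.random.default_rng(42)
    modes = np.array([[12.0, 12.0], [20.0, 18.0], [32.0, 30.0]])
    wh = np.vstack([m * r.lognormal(0, 0.12, (40, 2)) for m in modes])
    return wh


class TestRatioMetric:
    def test_exact_match_is_one(self):
        assert ratio_metric((10, 13), (10, 13)) == 1.0

    def test_uniform_double(self):
        assert ratio_metric((20, 20), (10, 10)) == 2.0

    def test_worst_dimension_dominates(self):
        assert ratio_metric((10, 40), (20, 20)) == 2.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ratio_metric((0, 10), (10, 10))


class TestAatBpr:
    def test_identical_anchors_saturate_aat(self):
        anchors = AnchorSet(np.tile([[15.0, 15.0]], (9, 1)))
        assert aat([[15, 15]], anchors) == 1.0

    def test_all_anchors_off_gives_zero(self):
        anchors = AnchorSet(np.tile([[100.0, 100.0]], (9, 1)))
        assert aat([[10, 10]], anchors) == 0.0
        assert bpr([[10, 10]], anchors) == 0.0

    def test_aat_matches_bruteforce_enumeration(self, clustered_boxes):
        anchors = AnchorSet.default()
        expected = np.mean([
            np.mean([ratio_metric(b, a) < anchors.ratio_threshold
                     for a in anchors.anchors])
            for b in clustered_boxes])
        assert aat(clustered_boxes, anchors) == pytest.approx(expected)

    def test_bpr_matches_bruteforce_enumeration(self, clustered_boxes):
        anchors = AnchorSet.default()
        expected = np.mean([
            min(ratio_metric(b, a) for a in anchors.anchors)
            < anchors.ratio_threshold
            for b in clustered_boxes])
        assert bpr(clustered_boxes, anchors) == pytest.approx(expected)

    def test_exact_anchor_copies_give_full_bpr(self, clustered_boxes):
        anchors = AnchorSet(np.unique(clustered_boxes[:9], axis=0))
        assert bpr(clustered_boxes[:9], anchors) == 1.0

    def test_single_far_anchor(self):
        anchors = AnchorSet(np.array([[100.0, 100.0]]))
        assert bpr([[10.0, 10.0]], anchors) == 0.0  # ratio 10 >= 4

    def test_order_invariance(self, clustered_boxes, rng):
        anchors = AnchorSet.default()
        shuffled = clustered_boxes[rng.permutation(len(clustered_boxes))]
        assert bpr(shuffled, anchors) == bpr(clustered_boxes, anchors)
        assert aat(shuffled, anchors) == aat(clustered_boxes, anchors)

    def test_adding_anchor_never_decreases_bpr(self, clustered_boxes):
        base = AnchorSet(np.array(DEFAULT_ANCHORS[:4], dtype=float))
        grown = AnchorSet(np.array(DEFAULT_ANCHORS[:5], dtype=float))
        assert bpr(clustered_boxes, grown) >= bpr(clustered_boxes, base)

    def test_bpr_monotone_in_ratio_threshold(self, clustered_boxes):
        vals = [bpr(clustered_boxes,
                    AnchorSet.default(ratio_threshold=t))
                for t in (1.5, 2.0, 3.0, 4.0)]
        assert vals == sorted(vals)

    def test_empty_boxes_rejected(self):
        with pytest.raises(ValueError):
            bpr(np.empty((0, 2)), AnchorSet.default())


class TestKmeans:
    def test_k_distinct_points_recovered(self):
        wh = np.array([[10.0, 12.0], [30.0, 28.0], [55.0, 60.0]])
        result = kmeans_anchors(wh, k=3, seed=0)
        assert np.allclose(np.sort(result.anchors, axis=0),
                           np.sort(wh, axis=0))

    def test_two_tight_clusters(self, rng):
        a = rng.normal([10, 10], 0.3, (40, 2))
        b = rng.normal([40, 45], 0.3, (40, 2))
        result = kmeans_anchors(np.vstack([a, b]), k=2, seed=1)
        got = result.anchors[np.argsort(result.anchors[:, 0])]
        assert np.abs(got[0] - a.mean(axis=0)).max() < 1.0
        assert np.abs(got[1] - b.mean(axis=0)).max() < 1.0

    def test_seed_determinism(self, clustered_boxes):
        r1 = kmeans_anchors(clustered_boxes, k=5, seed=9)
        r2 = kmeans_anchors(clustered_boxes, k=5, seed=9)
        assert np.array_equal(r1.anchors, r2.anchors)

    def test_objective_nonincreasing(self, clustered_boxes):
        _, history = kmeans_anchors(clustered_boxes, k=4, seed=2,
                                    return_history=True)
        assert all(a >= b - 1e-12 for a, b in zip(history, history[1:]))

    def test_reaches_exhaustive_oracle(self):
        """On 8 boxes with k=3 at least one of 10 seeds attains the
        globally optimal objective found by enumerating assignments."""
        r = np.random.default_rng(5)
        wh = r.uniform(5, 60, (8, 2))
        target = exhaustive_kmeans_objective(wh, 3)
        scale = wh.max(axis=0)
        gaps = []
        for seed in range(10):
            result = kmeans_anchors(wh, k=3, seed=seed)
            X, C = wh / scale, result.anchors / scale
            d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
            gaps.append(d2.min(axis=1).sum() - target)
        assert min(gaps) < 1e-6

    def test_too_few_distinct_boxes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_anchors(np.tile([[10.0, 10.0]], (20, 1)), k=3)


class TestGaRefine:
    def test_perfect_init_is_kept(self):
        wh = np.array([[10.0, 10.0], [20.0, 20.0], [40.0, 40.0]])
        init = AnchorSet(wh.copy())
        result = ga_refine(init, wh, generations=200, seed=0)
        assert anchor_fitness(result.anchors, wh, 4.0) == pytest.approx(
            anchor_fitness(init.anchors, wh, 4.0))

    def test_zero_generations_returns_init(self, clustered_boxes):
        init = AnchorSet(np.array(DEFAULT_ANCHORS, dtype=float))
        result = ga_refine(init, clustered_boxes, generations=0, seed=0)
        assert np.array_equal(result.anchors, init.anchors)

    def test_best_fitness_monotone(self, clustered_boxes):
        init = AnchorSet(kmeans_anchors(clustered_boxes, k=3,
                                        seed=0).anchors * 3.0)
        _, history = ga_refine(init, clustered_boxes, generations=300,
                               seed=3, return_history=True)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_improves_misscaled_init_across_seeds(self, clustered_boxes):
        """A x3 mis-scaled init improves in at least 49 of 50 seeded runs."""
        base = kmeans_anchors(clustered_boxes, k=3, seed=0).anchors
        improved = 0
        for seed in range(50):
            init = AnchorSet(base * 3.0)
            f0 = anchor_fitness(init.anchors, clustered_boxes, 4.0)
            result = ga_refine(init, clustered_boxes, generations=300,
                               seed=seed)
            if anchor_fitness(result.anchors, clustered_boxes, 4.0) > f0:
                improved += 1
        assert improved >= 49

    def test_seed_determinism(self, clustered_boxes):
        init = AnchorSet(np.array(DEFAULT_ANCHORS, dtype=float))
        a = ga_refine(init, clustered_boxes, generations=100, seed=7)
        b = ga_refine(init, clustered_boxes, generations=100, seed=7)
        assert np.array_equal(a.anchors, b.anchors)


class TestCheckAnchors:
    def test_defaults_kept_when_adequate(self, rng):
        base = np.array(DEFAULT_ANCHORS, dtype=float)
        boxes = np.vstack([a * rng.lognormal(0, 0.05, (10, 2))
                           for a in base])
        result = check_anchors(boxes, generations=50, seed=0)
        assert np.array_equal(result.anchors, base)

    def test_tiny_boxes_force_recalculation(self, rng):
        boxes = rng.uniform(2, 8, (100, 2))
        result = check_anchors(boxes, generations=200, seed=0)
        assert not np.array_equal(result.anchors,
                                  np.array(DEFAULT_ANCHORS, dtype=float))
        assert result.anchors.max() < 40.0

    def test_never_below_default_bpr(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            boxes = r.uniform(3, 400, (60, 2))
            result = check_anchors(boxes, generations=100, seed=seed)
            assert bpr(boxes, result) >= bpr(boxes, AnchorSet.default())
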