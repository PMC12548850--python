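"""Input layer contract, training schedule, matching, and P/R/F1 metrics."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fruitfusion.anchors import AnchorSet
from fruitfusion.detector import (Detection, InputLayerSpec, TrainConfig,
                                  box_iou, build_model, evaluate, f1,
                                  load_model, lr_at_epoch, match_detections,
                                  momentum_at_epoch, precision, recall,
                                  save_model, train)

SMALL_ANCHORS = AnchorSet(np.array([[10.0, 10.0], [18.0, 18.0],
                                    [28.0, 28.0]]))


def det(cx, cy, w, h, conf=1.0):
    return Detection(np.array([cx, cy, w, h], dtype=float), conf)


class TestInputLayer:
    @pytest.mark.parametrize("m", [3, 8])
    def test_first_layer_parameter_count(self, m):
        model = build_model(InputLayerSpec(m=m), SMALL_ANCHORS)
        assert model.input_layer.n_params == 6 * 6 * m * 32 + 32

    def test_channel_contract_enforced(self):
        m3 = build_model(InputLayerSpec(m=3), SMALL_ANCHORS)
        x3 = np.zeros((1, 3, 48, 48), dtype=np.float32)
        assert m3.forward(x3, train=False).shape[0] == 1
        m8 = build_model(InputLayerSpec(m=8), SMALL_ANCHORS)
        with pytest.raises(ValueError, match="8-channel"):
            m8.forward(x3, train=False)

    def test_downstream_shapes_independent_of_m(self):
        m3 = build_model(InputLayerSpec(m=3), SMALL_ANCHORS)
        m8 = build_model(InputLayerSpec(m=8), SMALL_ANCHORS)
        shapes3 = [l.weight.value.shape for l in m3.net.layers[2::2]
                   if hasattr(l, "weight")]
        shapes8 = [l.weight.value.shape for l in m8.net.layers[2::2]
                   if hasattr(l, "weight")]
        assert shapes3 == shapes8

    def test_m_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            InputLayerSpec(m=9)


class TestSchedule:
    def test_published_schedule_values(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 0) == pytest.approx(0.01)
        assert momentum_at_epoch(cfg, 1) == 0.8       # warm-up phase
        assert momentum_at_epoch(cfg, 3) == 0.937     # after warm-up
        # linear decay lands on lr0 * decay factor at the end
        assert lr_at_epoch(cfg, cfg.epochs) == pytest.approx(0.01 * 0.01)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=2, warmup_epochs=3)


class TestTraining:
    def test_loss_decreases_on_small_dataset(self):
        """Twenty synthetic scenes, five epochs: loss must drop."""
        from fruitfusion.pipeline import (PipelineConfig,
                                          build_detection_dataset)
        from fruitfusion.synth import make_dataset

        cfg = PipelineConfig()
        manifest = make_dataset(20, seed=0)
        dataset = build_detection_dataset(manifest, "train", cfg)
        model = build_model(InputLayerSpec(m=8), SMALL_ANCHORS, seed=0)
        _, history = train(model, dataset,
                           replace(cfg.train, epochs=5, seed=0))
        assert len(history) == 5
        assert history[-1] < history[0]

    def test_empty_dataset_rejected(self):
        model = build_model(InputLayerSpec(m=3), SMALL_ANCHORS)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(epochs=5))

    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(InputLayerSpec(m=5), SMALL_ANCHORS, seed=4)
        path = tmp_path / "weights.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.spec.m == 5
        x = np.random.default_rng(0).normal(
            size=(1, 5, 48, 48)).astype(np.float32)
        assert np.array_equal(model.forward(x, train=False),
                              back.forward(x, train=False))


class TestMatching:
    def test_perfect_predictions(self):
        truths = [[10, 10, 8, 8], [30, 30, 10, 10]]
        preds = [det(*t) for t in truths]
        assert match_detections(preds, truths) == (2, 0, 0)

    def test_no_predictions(self):
        assert match_detections([], [[10, 10, 8, 8]]) == (0, 0, 1)

    def test_one_to_one_rule(self):
        truths = [[10, 10, 8, 8]]
        preds = [det(10, 10, 8, 8, 0.9), det(11, 10, 8, 8, 0.8)]
        assert match_detections(preds, truths) == (1, 1, 0)

    def test_count_conservation(self, rng):
        for _ in range(20):
            n_t, n_p = rng.integers(0, 6, 2)
            truths = rng.uniform(5, 60, (n_t, 4))
            preds = [det(*rng.uniform(5, 60, 4), conf=rng.random())
                     for _ in range(n_p)]
            tp, fp, fn = match_detections(preds, truths)
            assert tp + fp == n_p and tp + fn == n_t

    def test_iou_threshold_validated(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_thr=1.5)

    def test_iou_of_disjoint_boxes_is_zero(self):
        assert box_iou([0, 0, 2, 2], [10, 10, 2, 2])[0, 0] == 0.0


class TestMetrics:
    @pytest.mark.parametrize("P,R,expected,places", [
        (79.7, 99.0, 88.31, 2),   # published worked example
        (95.8, 96.0, 95.9, 1),    # headline configuration
        (88.4, 98.0, 92.95, 2),
    ])
    def test_f1_matches_published_values(self, P, R, expected, places):
        assert round(f1(P, R), places) == pytest.approx(expected)

    def test_harmonic_mean_of_equals(self):
        assert f1(73.5, 73.5) == pytest.approx(73.5)

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    def test_f1_bounds_and_symmetry(self, p, r):
        v = f1(p, r)
        assert min(p, r) - 1e-9 <= v <= max(p, r) + 1e-9
        assert v == pytest.approx(f1(r, p))

    def test_zero_denominators_warn_to_zero(self):
        assert precision(0, 0) == 0.0
        assert recall(0, 0) == 0.0
        assert f1(0.0, 0.0) == 0.0

    def test_percentages(self):
        assert precision(3, 1) == pytest.approx(75.0)
        assert recall(3, 2) == pytest.approx(60.0)


class TestEvaluate:
    def _dataset(self, rng, n=4):
        out = []
        for _ in range(n):
            boxes = rng.uniform(10, 80, (int(rng.integers(1, 4)), 4))
            boxes[:, 2:] = rng.uniform(6, 15, boxes[:, 2:].shape)
            out.append(dict(image=rng.normal(size=(3, 96, 96))
                            .astype(np.float32), boxes=boxes))
        return out

    def test_oracle_detector_scores_100(self, rng):
        from fruitfusion.pipeline import OracleDetector

        dataset = self._dataset(rng)
        res = evaluate(OracleDetector(dataset), dataset)
        assert (res.P, res.R, res.F1) == (100.0, 100.0, 100.0)

    def test_silent_detector_has_zero_recall(self, rng):
        class Silent:
            def predict(self, image, conf_thr=0.25, nms_iou=0.45):
                return []

        res = evaluate(Silent(), self._dataset(rng))
        assert res.R == 0.0

    def test_metrics_match_per_image_recount(self, rng):
        class Half:
            def predict(self, image, conf_thr=0.25, nms_iou=0.45):
                return [det(20, 20, 10, 10, 0.9), det(70, 70, 10, 10, 0.4)]

        dataset = self._dataset(rng)
        res = evaluate(Half(), dataset)
        tp = sum(t for t, _, _ in res.per_image)
        fp = sum(f for _, f, _ in res.per_image)
        fn = sum(f for _, _, f in res.per_image)
        assert res.P == pytest.approx(precision(tp, fp))
        assert res.R == pytest.approx(recall(tp, fn))
        assert res.F1 == pytest.approx(f1(res.P, res.R))

    def test_empty_split_rejected(self):
        from fruitfusion.pipeline import OracleDetector

        with pytest.raises(ValueError):
            evaluate(OracleDetector([]), [])
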