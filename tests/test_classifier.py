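"""Metrics, augmentation, folds, open-set thresholds and feature maps."""

from __future__ import annotations

import numpy as np
import pytest

from pollenstack import classify as cl
from pollenstack import nn


# ---------------------------------------------------------------------------
# metrics against a brute-force oracle
# ---------------------------------------------------------------------------

def brute_metrics(counts: np.ndarray):
    """Re-derive per-class measures by looping over all (true, pred) pairs."""
    k = counts.shape[0]
    pairs = [
        (t, p) for t in range(k) for p in range(k) for _ in range(int(counts[t, p]))
    ]
    total = len(pairs)
    out = {}
    for c in range(k):
        tp = sum(1 for t, p in pairs if t == c and p == c)
        fp = sum(1 for t, p in pairs if t != c and p == c)
        fn = sum(1 for t, p in pairs if t == c and p != c)
        tn = total - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = dict(tp=tp, fp=fp, fn=fn, tn=tn, precision=prec, recall=rec, f1=f1)
    out["ccr"] = sum(1 for t, p in pairs if t == p) / total
    supports = [sum(1 for t, _ in pairs if t == c) for c in range(k)]
    out["weighted_recall"] = sum(
        out[c]["recall"] * supports[c] / total for c in range(k)
    )
    return out


def test_perfect_classifier_metrics_are_one():
    cm = cl.ConfusionMatrix(np.diag([5, 7, 9]), cl.CLASS_LABELS)
    m = cl.compute_metrics(cm)
    assert m.ccr == 1.0
    assert (m.per_class[["precision", "recall", "f1"]] == 1.0).all().all()
    assert m.weighted_f1 == 1.0


def test_two_class_hand_computed_example():
    """cm [[8,2],[3,7]]: precision0 = 8/11, recall0 = 0.8, CCR = 0.75."""
    cm = cl.ConfusionMatrix(np.array([[8, 2], [3, 7]]), ("a", "b"))
    m = cl.compute_metrics(cm)
    assert m.per_class.loc["a", "precision"] == pytest.approx(8 / 11)
    assert m.per_class.loc["a", "recall"] == pytest.approx(0.8)
    assert m.ccr == pytest.approx(0.75)


@pytest.mark.parametrize("seed", range(4))
def test_metrics_match_brute_force_on_random_matrices(seed):
    rng = np.random.default_rng(seed)
    for _ in range(25):
        k = int(rng.integers(2, 5))
        counts = rng.integers(0, 20, (k, k))
        while counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
            counts = rng.integers(1, 20, (k, k))
        cm = cl.ConfusionMatrix(counts, tuple(f"c{i}" for i in range(k)))
        mine = cl.compute_metrics(cm)
        ref = brute_metrics(counts)
        for i, lab in enumerate(cm.labels):
            for key in ("tp", "fp", "fn", "tn"):
                assert mine.per_class.loc[lab, key] == ref[i][key]
            assert mine.per_class.loc[lab, "precision"] == pytest.approx(ref[i]["precision"])
            assert mine.per_class.loc[lab, "f1"] == pytest.approx(ref[i]["f1"])
        assert mine.ccr == pytest.approx(ref["ccr"])
        # identity: weighted recall equals CCR on complete matrices
        assert mine.weighted_recall == pytest.approx(mine.ccr)
        assert mine.weighted_recall == pytest.approx(ref["weighted_recall"])


def test_zero_division_flagged_not_raised():
    cm = cl.ConfusionMatrix(np.array([[5, 0], [3, 0]]), ("a", "b"))
    m = cl.compute_metrics(cm)
    assert m.per_class.loc["b", "precision"] == 0.0
    assert any("b" in f for f in m.zero_division_flags)


def test_empty_confusion_matrix_errors():
    with pytest.raises(ValueError):
        cl.compute_metrics(cl.ConfusionMatrix(np.zeros((2, 2)), ("a", "b")))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rand_frames(n=4, seed=0):
    return np.random.default_rng(seed).random((n, 16, 16, 3)).astype(np.float32)


def test_augment_identity_when_disabled():
    cfg = cl.AugmentConfig(brightness_range=(1.0, 1.0), horizontal_flip=False, vertical_flip=False)
    x = _rand_frames()
    out = cl.augment_batch(x, cfg, np.random.default_rng(0))
    np.testing.assert_allclose(out, x, atol=1e-7)


def test_double_horizontal_flip_is_identity():
    x = _rand_frames(1)[0]
    np.testing.assert_array_equal(x[:, ::-1][:, ::-1], x)


def test_brightness_monotonicity():
    x = _rand_frames()
    dark = cl.AugmentConfig(brightness_range=(1.0, 1.0))
    rng = np.random.default_rng(0)
    base = cl.augment_batch(x, dark, rng).mean()
    out_dark = np.clip(x * 0.1, 0, 1)
    out_bright = np.clip(x * 2.0, 0, 1)
    assert out_dark.mean() < base
    assert out_bright.mean() >= base


def test_augment_config_validation():
    with pytest.raises(ValueError):
        cl.AugmentConfig(brightness_range=(1.5, 2.0))


def test_augment_preserves_shape_and_scale_metadata():
    from pollenstack.stack_io import FramedImage

    fi = FramedImage(
        pixels=np.random.default_rng(1).random((276, 276, 3)).astype(np.float32),
        pixel_size_um=0.16,
    )
    out = cl.augment(fi, cl.AugmentConfig(), np.random.default_rng(2))
    assert out.pixels.shape == (276, 276, 3)
    assert out.pixel_size_um == 0.16


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def test_scratch_build_is_deterministic_given_seed():
    cfg = cl.TrainConfig(seed=5)
    a, b = cl.build_model(cfg), cl.build_model(cfg)
    for la, lb in zip(a.layers, b.layers, strict=True):
        for key in la.params:
            np.testing.assert_array_equal(la.params[key], lb.params[key])


def test_model_outputs_are_probabilities():
    model = cl.build_model(cl.TrainConfig(seed=1))
    x = np.random.default_rng(0).random((2, 276, 276, 3)).astype(np.float32)
    probs = model.predict_proba(x)
    assert probs.shape == (2, 3)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)
    assert (probs >= 0).all()


def test_tiny_test_single_forward_is_fast():
    import time

    model = cl.build_model(cl.TrainConfig(seed=0))
    x = np.zeros((1, 276, 276, 3), dtype=np.float32)
    model.predict_proba(x)  # warm-up
    t0 = time.time()
    model.predict_proba(x)
    assert time.time() - t0 < 1.0


def test_pretrained_without_weights_is_an_error():
    with pytest.raises(ValueError, match="weight file"):
        cl.build_model(cl.TrainConfig(mode="pretrained"))


def test_pretrained_round_trips_saved_weights(tmp_path):
    cfg = cl.TrainConfig(seed=3)
    model = cl.build_model(cfg)
    model.save_weights(tmp_path / "w.npz")
    loaded = cl.build_model(
        cl.TrainConfig(seed=99, mode="pretrained", pretrained_weights=str(tmp_path / "w.npz"))
    )
    x = np.random.default_rng(0).random((1, 276, 276, 3)).astype(np.float32)
    np.testing.assert_allclose(model.predict_proba(x), loaded.predict_proba(x), rtol=1e-5)


# ---------------------------------------------------------------------------
# cross-validation mechanics (stub models keep this fast)
# ---------------------------------------------------------------------------

class _ConstantModel:
    """Always predicts the first class with fixed confidence."""

    def __init__(self, scores=(0.8, 0.15, 0.05)):
        self.scores = np.asarray(scores, dtype=float)

    def fit(self, *a, **k):
        return []

    def predict_proba(self, x, batch_size=64):
        return np.tile(self.scores, (len(x), 1))


def _tiny_dataset(n_per_class=10, px=8, seed=0):
    rng = np.random.default_rng(seed)
    frames = rng.random((3 * n_per_class, px, px, 3)).astype(np.float32)
    labels = [lab for lab in cl.CLASS_LABELS for _ in range(n_per_class)]
    return frames, labels


def test_folds_partition_dataset_exactly():
    frames, labels = _tiny_dataset(10)
    cfg = cl.TrainConfig(k_folds=5, epochs=1, seed=0)
    res = cl.crossvalidate(frames, labels, cfg, model_factory=lambda s: _ConstantModel())
    all_val = np.concatenate([f.val_indices for f in res.folds])
    assert sorted(all_val) == list(range(len(frames)))
    for f in res.folds:
        assert f.confusion.counts.sum() == 6  # 2 per class with 10 per class
    assert res.pooled_confusion.counts.sum() == len(frames)


def test_always_first_class_stub_gives_one_third_ccr():
    frames, labels = _tiny_dataset(10)
    cfg = cl.TrainConfig(k_folds=5, epochs=1, seed=0)
    res = cl.crossvalidate(frames, labels, cfg, model_factory=lambda s: _ConstantModel())
    assert res.pooled_metrics.ccr == pytest.approx(1 / 3)


def test_too_few_images_per_class_errors():
    frames, labels = _tiny_dataset(3)
    with pytest.raises(ValueError, match="fewer than"):
        cl.crossvalidate(frames, labels, cl.TrainConfig(k_folds=5, epochs=1))


def test_folds_reproducible_from_seed():
    frames, labels = _tiny_dataset(10)
    cfg = cl.TrainConfig(k_folds=5, epochs=1, seed=7)
    r1 = cl.crossvalidate(frames, labels, cfg, model_factory=lambda s: _ConstantModel())
    r2 = cl.crossvalidate(frames, labels, cfg, model_factory=lambda s: _ConstantModel())
    for f1, f2 in zip(r1.folds, r2.folds, strict=True):
        np.testing.assert_array_equal(f1.val_indices, f2.val_indices)


def test_grouped_folds_keep_plants_together():
    frames, labels = _tiny_dataset(10)
    groups = [f"{lab}_plant{i % 5}" for i, lab in enumerate(labels)]
    cfg = cl.TrainConfig(k_folds=5, epochs=1, seed=1, group_by_sample=True)
    res = cl.crossvalidate(
        frames, labels, cfg, groups=groups, model_factory=lambda s: _ConstantModel()
    )
    group_arr = np.asarray(groups)
    for f in res.folds:
        val_groups = set(group_arr[f.val_indices])
        train_idx = np.setdiff1d(np.arange(len(frames)), f.val_indices)
        assert not (val_groups & set(group_arr[train_idx]))


# ---------------------------------------------------------------------------
# open-set prediction and test-case aggregation
# ---------------------------------------------------------------------------

def _pred(scores, threshold):
    return cl.Prediction(scores=np.asarray(scores), labels=cl.CLASS_LABELS, threshold=threshold)


def test_threshold_rule_on_top_score():
    assert _pred((0.55, 0.30, 0.15), 0.60).assigned == cl.UNKNOWN
    assert _pred((0.85, 0.10, 0.05), 0.60).assigned == "urtica"
    assert _pred((0.34, 0.33, 0.33), 0.0).assigned == "urtica"  # threshold 0: never unknown
    assert _pred((0.99, 0.005, 0.005), 1.01).assigned == cl.UNKNOWN  # > 1: always unknown


def test_unknown_rate_monotone_in_threshold():
    rng = np.random.default_rng(0)
    raw = rng.random((200, 3))
    scores = raw / raw.sum(axis=1, keepdims=True)
    preds = [_pred(s, 0.6) for s in scores]
    report = cl.summarize_test_cases({"s1": preds}, thresholds=(0.0, 0.3, 0.6, 0.7, 0.9))
    unknown_by_thr = [
        report.table.loc[report.table["threshold"] == t, "pct_unknown"].iloc[0]
        for t in (0.0, 0.3, 0.6, 0.7, 0.9)
    ]
    assert unknown_by_thr == sorted(unknown_by_thr)


def test_single_class_sample_at_zero_threshold():
    preds = [_pred((0.9, 0.06, 0.04), 0.0) for _ in range(20)]
    report = cl.summarize_test_cases({"only": preds}, thresholds=(0.0,))
    row = report.table.iloc[0]
    assert row["pct_urtica"] == 100.0
    assert row["pct_unknown"] == 0.0
    assert row["n"] == 20


def test_percentages_sum_to_hundred_up_to_rounding():
    rng = np.random.default_rng(5)
    raw = rng.random((37, 3))
    preds = [_pred(s / s.sum(), 0.6) for s in raw]
    report = cl.summarize_test_cases({"s": preds}, thresholds=(0.6,))
    row = report.table.iloc[0]
    total = row[[c for c in report.table.columns if c.startswith("pct_")]].sum()
    assert abs(total - 100.0) < 0.3


def test_empty_groups_error():
    with pytest.raises(ValueError):
        cl.summarize_test_cases({})
    with pytest.raises(ValueError):
        cl.summarize_test_cases({"s": []})


# ---------------------------------------------------------------------------
# feature maps
# ---------------------------------------------------------------------------

def test_feature_map_count_and_resolution_ordering():
    model = cl.build_model(cl.TrainConfig(seed=2))
    frame = np.random.default_rng(1).random((276, 276, 3)).astype(np.float32)
    maps1 = cl.export_feature_maps(model, frame, "conv1")
    maps3 = cl.export_feature_maps(model, frame, "conv3")
    assert len(maps1) == 12 and len(maps3) == 48
    assert maps1[0].shape[0] > maps3[0].shape[0]  # earlier layer: finer resolution
    for m in maps1:
        assert 0.0 <= m.min() and m.max() <= 1.0


def test_feature_maps_unknown_layer_errors():
    model = cl.build_model(cl.TrainConfig(seed=2))
    with pytest.raises(KeyError, match="conv9"):
        cl.export_feature_maps(model, np.zeros((276, 276, 3), dtype=np.float32), "conv9")


def test_all_zero_input_gives_constant_activations():
    model = cl.build_model(cl.TrainConfig(seed=2))
    maps = cl.export_feature_maps(model, np.zeros((276, 276, 3), dtype=np.float32), "conv1")
    for m in maps:
        assert np.ptp(m) == 0.0
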