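"""Training, cross-validation and open-set application of the classifier.

The classification task is 3-way (Urtica / Parietaria / Urtica
membranacea) over framed projection images, with an *identity
threshold*: a grain whose top softmax score falls below the threshold is
reported as ``unknown`` rather than forced into a class — the behaviour
required when the model meets aerobiological samples full of debris and
out-of-library taxa.

Evaluation follows standard monitoring practice: stratified k-fold
cross-validation (fivefold = 80/20 split per fold, tenfold = 90/10),
online augmentation of training images only (random horizontal and
vertical flips plus a brightness factor in [0.1, 2] — geometry-changing
augmentations are excluded because size and shape are class features),
and per-class one-vs-rest precision / recall / F1 plus the correct
classification rate (CCR), averaged weighted by class support.

Architectures: ``tiny_test`` is a deliberately small network for
CPU-scale runs and continuous testing; ``light_v1``/``light_v2`` are
mid-size plain-conv networks and ``deep_baseline`` a deeper stack of
small-kernel convolution blocks.  None of them reproduces a published backbone; ``pretrained``
mode exists for externally supplied weight files and fails loudly when
none is given.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import nn
from .stack_io import FRAME_PX, FramedImage

log = logging.getLogger(__name__)

CLASS_LABELS = ("urtica", "parietaria", "membranacea")
UNKNOWN = "unknown"

ARCHITECTURES = ("deep_baseline", "light_v1", "light_v2", "tiny_test")


@dataclass
class TrainConfig:
    """Training and cross-validation settings."""

    architecture: str = "tiny_test"
    mode: str = "scratch"  # or "pretrained"
    k_folds: int = 5
    epochs: int = 30
    l2_weight: float = 1e-4
    dropout_rate: float = 0.25
    learning_rate: float = 3e-3  # not a published value; package default
    batch_size: int = 32  # not a published value; package default
    seed: int = 0
    group_by_sample: bool = True
    pretrained_weights: str | None = None

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.mode not in ("scratch", "pretrained"):
            raise ValueError("mode must be 'scratch' or 'pretrained'")
        if self.k_folds not in (5, 10):
            raise ValueError("k_folds must be 5 (80/20 folds) or 10 (90/10 folds)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class AugmentConfig:
    """Morphology-preserving augmentation: flips and brightness only."""

    brightness_range: tuple[float, float] = (0.1, 2.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.brightness_range
        if not (0 < lo <= 1 <= hi):
            raise ValueError("brightness_range must satisfy 0 < low <= 1 <= high")


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _conv_block(spec, rng):
    layers = []
    in_ch = spec[0]
    idx = 1
    for out_ch in spec[1:]:
        layers.append(nn.Conv2D(in_ch, out_ch, 3, rng, name=f"conv{idx}"))
        layers.append(nn.ReLU(name=f"relu{idx}"))
        layers.append(nn.MaxPool2(name=f"pool{idx}"))
        in_ch = out_ch
        idx += 1
    return layers, in_ch


def _spatial_after(input_px: int, stem: int, n_pools: int) -> int:
    s = input_px // stem
    for _ in range(n_pools):
        s //= 2
    return s


def build_model(
    config: TrainConfig,
    input_px: int = FRAME_PX,
    n_classes: int = len(CLASS_LABELS),
) -> nn.Network:
    """Construct a network; scratch mode is seeded, pretrained loads weights.

    Requesting ``pretrained`` without a weight file is an error — the
    model never falls back silently to random initialisation.
    """
    rng = np.random.default_rng(config.seed)
    arch = config.architecture
    if arch == "tiny_test":
        stem, channels, dense_units = 4, (3, 12, 24, 48), 64
    elif arch == "light_v1":
        stem, channels, dense_units = 2, (3, 16, 32, 64), 64
    elif arch == "light_v2":
        stem, channels, dense_units = 2, (3, 16, 32, 64, 64), 96
    else:  # deep_baseline
        stem, channels, dense_units = 1, (3, 16, 32, 64, 128, 128), 128
    layers: list[nn.Layer] = [nn.InstanceNorm(name="norm")]
    if stem > 1:
        layers.append(nn.AvgPool(stem, name="stem"))
    conv_layers, last_ch = _conv_block(channels, rng)
    layers.extend(conv_layers)
    side = _spatial_after(input_px, stem, len(channels) - 1)
    layers.append(nn.Flatten(name="flatten"))
    layers.append(nn.Dense(side * side * last_ch, dense_units, rng, name="dense1"))
    layers.append(nn.ReLU(name="relu_dense"))
    layers.append(nn.Dropout(config.dropout_rate, name="dropout"))
    layers.append(nn.Dense(dense_units, n_classes, rng, name="dense2"))
    model = nn.Network(layers=layers, n_classes=n_classes, l2_weight=config.l2_weight)
    if config.mode == "pretrained":
        if not config.pretrained_weights:
            raise ValueError(
                "pretrained mode requires an externally supplied weight file; "
                "no silent fallback to random initialisation"
            )
        model.load_weights(config.pretrained_weights)
    return model


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_batch(
    batch: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random flips + one brightness factor per image, clipped to [0, 1]."""
    out = batch.copy()
    n = len(out)
    if config.horizontal_flip:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, ::-1]
    if config.vertical_flip:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, ::-1]
    lo, hi = config.brightness_range
    factors = rng.uniform(lo, hi, n)[:, None, None, None].astype(out.dtype, copy=False)
    return np.clip(out * factors, 0.0, 1.0)


def augment(image: FramedImage, config: AugmentConfig, rng: np.random.Generator) -> FramedImage:
    """Augment a single framed image (shape and pixel scale unchanged)."""
    pixels = augment_batch(image.pixels[np.newaxis].astype(np.float64), config, rng)[0]
    return FramedImage(
        pixels=pixels.astype(image.pixels.dtype),
        pixel_size_um=image.pixel_size_um,
        channel_roles=image.channel_roles,
        provenance=dict(image.provenance),
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
    ) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, labels=tuple(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass
class Metrics:
    """Per-class one-vs-rest counts and measures, plus weighted averages."""

    per_class: pd.DataFrame  # index: label; columns tp/fp/fn/tn/precision/recall/f1/support
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    ccr: float
    zero_division_flags: list[str] = field(default_factory=list)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R),
    CCR = (TP+TN)/total = trace/total; weighted averages use class
    supports (row sums) as weights.  Division by zero yields 0 with a
    logged flag."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []

    def safe_div(num: float, den: float, what: str) -> float:
        if den == 0:
            flags.append(what)
            log.warning("compute_metrics: %s undefined (0/0); reporting 0", what)
            return 0.0
        return num / den

    rows = []
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        tn = total - tp - fp - fn
        precision = safe_div(tp, tp + fp, f"precision[{label}]")
        recall = safe_div(tp, tp + fn, f"recall[{label}]")
        f1 = safe_div(2 * precision * recall, precision + recall, f"f1[{label}]")
        rows.append(
            {
                "label": label,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "support": tp + fn,
            }
        )
    per_class = pd.DataFrame(rows).set_index("label")
    weights = per_class["support"] / total
    return Metrics(
        per_class=per_class,
        weighted_precision=float((per_class["precision"] * weights).sum()),
        weighted_recall=float((per_class["recall"] * weights).sum()),
        weighted_f1=float((per_class["f1"] * weights).sum()),
        ccr=float(np.trace(counts) / total),
        zero_division_flags=flags,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    confusion: ConfusionMatrix
    metrics: Metrics
    val_indices: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: Metrics

    @property
    def fold_mean_ccr(self) -> float:
        return float(np.mean([f.metrics.ccr for f in self.folds]))


def crossvalidate(
    frames: np.ndarray,
    labels: Sequence[str],
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
    groups: Sequence[str] | None = None,
    model_factory: Callable[[int], "nn.Network"] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation with leakage control.

    Each image is validated exactly once; augmentation touches training
    portions only.  When ``groups`` (plant/sample identifiers) are given
    and ``train_cfg.group_by_sample`` is set, folds keep all images of
    one plant together, which is stricter than plain stratification.
    ``model_factory(fold_seed)`` may replace the default architecture
    (used for stub classifiers in validation experiments).
    """
    frames = np.asarray(frames)
    y = np.asarray([CLASS_LABELS.index(lab) for lab in labels])
    class_counts = np.bincount(y, minlength=len(CLASS_LABELS))
    if (class_counts < train_cfg.k_folds).any() and (groups is None or not train_cfg.group_by_sample):
        small = [CLASS_LABELS[i] for i in np.where(class_counts < train_cfg.k_folds)[0]]
        raise ValueError(f"classes with fewer than k={train_cfg.k_folds} images: {small}")
    aug_cfg = aug_cfg or AugmentConfig()

    if groups is not None and train_cfg.group_by_sample:
        splitter = StratifiedGroupKFold(
            n_splits=train_cfg.k_folds, shuffle=True, random_state=train_cfg.seed
        )
        split_iter = splitter.split(frames, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(
            n_splits=train_cfg.k_folds, shuffle=True, random_state=train_cfg.seed
        )
        split_iter = splitter.split(frames, y)

    folds: list[FoldResult] = []
    seen = np.zeros(len(frames), dtype=bool)
    for fold, (train_idx, val_idx) in enumerate(split_iter):
        assert not np.intersect1d(train_idx, val_idx).size, "fold leakage"
        assert not seen[val_idx].any(), "image validated twice"
        seen[val_idx] = True
        fold_seed = train_cfg.seed + 1000 * (fold + 1)
        rng = np.random.default_rng(fold_seed)
        if model_factory is not None:
            model = model_factory(fold_seed)
        else:
            model = build_model(
                TrainConfig(**{**train_cfg.__dict__, "seed": fold_seed})
            )
        aug_fn = lambda batch, r: augment_batch(batch, aug_cfg, r)  # noqa: E731
        model.fit(
            frames[train_idx],
            y[train_idx],
            epochs=train_cfg.epochs,
            batch_size=train_cfg.batch_size,
            learning_rate=train_cfg.learning_rate,
            rng=rng,
            augment_fn=aug_fn,
        )
        probs = model.predict_proba(frames[val_idx])
        pred = [CLASS_LABELS[i] for i in probs.argmax(axis=1)]
        true = [CLASS_LABELS[i] for i in y[val_idx]]
        cm = ConfusionMatrix.from_predictions(true, pred, CLASS_LABELS)
        folds.append(
            FoldResult(fold=fold, confusion=cm, metrics=compute_metrics(cm), val_indices=val_idx)
        )
    assert seen.all(), "cross-validation did not cover the dataset"
    pooled = folds[0].confusion
    for f in folds[1:]:
        pooled = pooled + f.confusion
    return CVResult(folds=folds, pooled_confusion=pooled, pooled_metrics=compute_metrics(pooled))


def train_model(
    frames: np.ndarray,
    labels: Sequence[str],
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
) -> nn.Network:
    """Train one model on the full labelled set (no held-out fold)."""
    y = np.asarray([CLASS_LABELS.index(lab) for lab in labels])
    aug_cfg = aug_cfg or AugmentConfig()
    model = build_model(train_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    model.fit(
        np.asarray(frames),
        y,
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate,
        rng=rng,
        augment_fn=lambda batch, r: augment_batch(batch, aug_cfg, r),
    )
    return model


# ---------------------------------------------------------------------------
# open-set prediction and test-case reports
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Class scores plus the open-set assignment at one threshold."""

    scores: np.ndarray  # per-class, sums to 1
    labels: tuple[str, ...]
    threshold: float

    @property
    def top_index(self) -> int:
        return int(np.argmax(self.scores))

    @property
    def top_label(self) -> str:
        return self.labels[self.top_index]

    @property
    def top_score(self) -> float:
        return float(self.scores[self.top_index])

    @property
    def assigned(self) -> str:
        return self.top_label if self.top_score >= self.threshold else UNKNOWN


def predict_with_threshold(
    model: nn.Network,
    frames: np.ndarray,
    threshold: float = 0.60,
    labels: Sequence[str] = CLASS_LABELS,
) -> list[Prediction]:
    """Score frames and apply the identity threshold to the top score."""
    probs = model.predict_proba(np.asarray(frames))
    return [
        Prediction(scores=p, labels=tuple(labels), threshold=threshold) for p in probs
    ]


@dataclass
class TestCaseReport:
    """Per-sample composition table plus mean unknown rate per threshold.

    ``table`` columns: sample, threshold, n, one ``pct_<class>`` column
    per class, ``pct_unknown`` (all percentages to 1 decimal).  The
    per-sample percentages sum to 100 up to rounding; the mean unknown
    rate is the unweighted average over samples.
    """

    table: pd.DataFrame
    mean_unknown_pct: dict[float, float]


def summarize_test_cases(
    predictions_by_sample: Mapping[str, Sequence[Prediction]],
    thresholds: Sequence[float] = (0.60, 0.70),
) -> TestCaseReport:
    """Aggregate per-grain predictions into per-sample composition rows."""
    if not predictions_by_sample:
        raise ValueError("no sample groups given")
    rows = []
    mean_unknown: dict[float, float] = {}
    for threshold in thresholds:
        per_sample_unknown = []
        for sample, preds in predictions_by_sample.items():
            if len(preds) == 0:
                raise ValueError(f"sample {sample!r} has no predictions")
            labels = preds[0].labels
            assigned = [
                p.top_label if p.top_score >= threshold else UNKNOWN for p in preds
            ]
            n = len(assigned)
            row: dict = {"sample": sample, "threshold": threshold, "n": n}
            for lab in labels:
                row[f"pct_{lab}"] = round(100.0 * assigned.count(lab) / n, 1)
            pct_unknown = round(100.0 * assigned.count(UNKNOWN) / n, 1)
            row["pct_unknown"] = pct_unknown
            per_sample_unknown.append(pct_unknown)
            rows.append(row)
        mean_unknown[threshold] = round(float(np.mean(per_sample_unknown)), 1)
    return TestCaseReport(table=pd.DataFrame(rows), mean_unknown_pct=mean_unknown)


# ---------------------------------------------------------------------------
# feature maps
# ---------------------------------------------------------------------------

def export_feature_maps(
    model: nn.Network,
    frame: np.ndarray | FramedImage,
    layer_name: str,
) -> list[np.ndarray]:
    """Per-channel activation images of a named layer, min–max scaled.

    White means high activation; a constant activation map (e.g. from an
    all-zero input through a bias-free path) scales to all zeros.
    """
    pixels = frame.pixels if isinstance(frame, FramedImage) else np.asarray(frame)
    act = model.activations(pixels[np.newaxis].astype(np.float64), layer_name)[0]
    if act.ndim != 3:
        raise ValueError(f"layer {layer_name!r} is not spatial (shape {act.shape})")
    maps = []
    for c in range(act.shape[-1]):
        channel = act[..., c]
        lo, hi = float(channel.min()), float(channel.max())
        maps.append(
            (channel - lo) / (hi - lo) if hi > lo else np.zeros_like(channel)
        )
    return maps
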