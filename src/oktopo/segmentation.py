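"""Training, inference, augmentation and evaluation for the segmentation nets.

The loss is the mean binary cross-entropy over all pixels of both output
channels (pupil and treatment zone are supervised independently because the
regions overlap).  Deep-supervision heads, when present, contribute equally:
the loss is the unweighted mean over heads.

Metrics are the standard pixel-classification quartet — precision, recall,
F1 and IoU — computed from TP/FP/FN pixel counts per region.  The k-fold
harness retrains a fresh model per fold and reports a per-fold table plus
the mean, micro-averaging pixel counts within each fold.
"""

from __future__ import annotations

import time
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize, rotate

from .models import _SegModel, build_model, SegModelConfig
from .nn import Adam, backward_multi
from .types import (
    PUPIL,
    TREATMENT_ZONE,
    RegionMask,
    as_image_array,
    as_mask_array,
)

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainResult",
    "SegMetrics",
    "ce_loss",
    "train",
    "train_test_split",
    "predict_masks",
    "augment",
    "seg_metrics",
    "kfold_evaluate",
]


@dataclass
class TrainConfig:
    """Optimisation settings.

    The defaults are the grid-search winners of the original clinical run
    (Adam, learning rate 1e-4, batch 32, 224×224 inputs, 100 epochs); the
    synthetic experiments use smaller values throughout.
    """

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    input_size_px: int = 224
    optimizer: str = "adam"
    seed: int = 0
    augment: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.input_size_px % 16:
            raise ValueError("input_size_px must be divisible by 16")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class TrainResult:
    loss_history: list[float]
    model: _SegModel
    seconds: float


def ce_loss(pred_probs: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over every pixel of every channel.

    ``pred_probs`` and ``target`` must have identical shapes; targets are
    binary, predictions are probabilities (clamped to [eps, 1-eps]).
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    r = np.asarray(target, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {r.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(r * np.log(p) + (1.0 - r) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# sample handling

def _sample_xy(sample) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a dataset sample to (H×W×3 uint8 image, 2×H×W {0,1} masks).

    Accepts a SyntheticCase-like object (``image``/``pupil_mask``/``tz_mask``
    attributes) or an ``(image, masks)`` tuple where masks is a 2×H×W array,
    a (pupil, tz) pair, or a dict keyed by role.
    """
    if hasattr(sample, "pupil_mask") and hasattr(sample, "tz_mask"):
        img = as_image_array(sample.image)
        masks = np.stack(
            [as_mask_array(sample.pupil_mask), as_mask_array(sample.tz_mask)]
        )
        return img, masks
    img, m = sample
    img = as_image_array(img)
    if isinstance(m, dict):
        masks = np.stack([as_mask_array(m[PUPIL]), as_mask_array(m[TREATMENT_ZONE])])
    else:
        m = list(m) if not isinstance(m, np.ndarray) else m
        if isinstance(m, np.ndarray) and m.ndim == 3:
            masks = np.stack([as_mask_array(m[0]), as_mask_array(m[1])])
        else:
            masks = np.stack([as_mask_array(m[0]), as_mask_array(m[1])])
    return img, masks


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    # standardise network inputs: zero-centred, roughly unit variance
    scaled = img.astype(np.float32) / 255.0
    if img.shape[0] != size or img.shape[1] != size:
        scaled = resize(scaled, (size, size), order=1, anti_aliasing=True,
                        preserve_range=True).astype(np.float32)
    return (scaled - 0.5) * 4.0


def _resize_masks(masks: np.ndarray, size: int) -> np.ndarray:
    """Training targets on the network grid: fractional pixel coverage.

    Downsampling with averaging keeps sub-grid boundary information in the
    targets (values in [0, 1] near region edges), which the bilinear
    upsampling in :func:`predict_masks` then exploits.
    """
    if masks.shape[1] == size and masks.shape[2] == size:
        return masks.astype(np.float32)
    out = np.stack([
        resize(m.astype(np.float32), (size, size), order=1, anti_aliasing=True,
               preserve_range=True)
        for m in masks
    ])
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _prepare(dataset, size: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for sample in dataset:
        img, masks = _sample_xy(sample)
        xs.append(_resize_image(img, size))
        ys.append(_resize_masks(masks, size).transpose(1, 2, 0))  # HWC, like the nets
    return np.stack(xs), np.stack(ys)


def train_test_split(dataset, test_fraction: float = 0.2, seed: int = 0):
    """Seeded random split; returns (train_list, test_list)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    idx = np.random.default_rng(seed).permutation(len(dataset))
    n_test = max(1, int(round(len(dataset) * test_fraction)))
    test_idx = set(idx[:n_test].tolist())
    train = [s for i, s in enumerate(dataset) if i not in test_idx]
    test = [s for i, s in enumerate(dataset) if i in test_idx]
    return train, test


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def train(dataset, model: _SegModel, tc: TrainConfig) -> TrainResult:
    """Optimise the model's BCE loss with Adam; returns the loss history.

    All shuffling and (optional) augmentation randomness derives from
    ``tc.seed``, so two runs with identical inputs coincide up to platform
    float determinism.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if tc.batch_size > len(dataset):
        raise ValueError(
            f"batch_size {tc.batch_size} exceeds dataset size {len(dataset)}"
        )
    rng = np.random.default_rng(tc.seed)
    if tc.augment:
        raw = [_sample_xy(s) for s in dataset]
    X, Y = _prepare(dataset, tc.input_size_px)
    params = model.parameters()
    opt = Adam(params, lr=tc.learning_rate)
    n = len(dataset)
    history: list[float] = []
    t0 = time.time()
    for epoch in range(tc.epochs):
        if tc.augment:
            aug = [augment(img, masks, seed=int(rng.integers(2**31)))
                   for img, masks in raw]
            X = np.stack([_resize_image(a[0], tc.input_size_px) for a in aug])
            Y = np.stack([_resize_masks(a[1], tc.input_size_px).transpose(1, 2, 0)
                          for a in aug])
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n - tc.batch_size + 1, tc.batch_size):
            sel = perm[start : start + tc.batch_size]
            xb, yb = X[sel], Y[sel]
            heads = model.forward(xb, training=True)
            probs = [_sigmoid(h.data) for h in heads]
            losses = [ce_loss(p, yb) for p in probs]
            seeds = [(p - yb) / (yb.size * len(heads)) for p in probs]
            opt.zero_grad()
            backward_multi(heads, seeds)
            opt.step()
            epoch_losses.append(float(np.mean(losses)))
        history.append(float(np.mean(epoch_losses)))
        log.debug("epoch %d/%d loss %.5f", epoch + 1, tc.epochs, history[-1])
    model.input_size_px = tc.input_size_px
    return TrainResult(loss_history=history, model=model, seconds=time.time() - t0)


def predict_masks(
    model: _SegModel,
    image,
    threshold: float = 0.5,
    input_size: int | None = None,
) -> tuple[RegionMask, RegionMask]:
    """Segment one topography into (pupil, treatment-zone) masks.

    The image is resized to the network grid and the per-channel
    probability maps are interpolated back (bilinear) to the native
    resolution *before* thresholding, so region boundaries keep sub-grid
    accuracy and downstream px→mm geometry uses the original scale.
    """
    img = as_image_array(image)
    size = input_size or model.input_size_px
    if size is None:
        raise ValueError("model has no recorded input size; pass input_size=")
    x = _resize_image(img, size)[None]
    proba = model.predict_proba(x)[0]  # (H, W, 2)
    h, w = img.shape[:2]
    out = []
    for ch, role in zip(proba.transpose(2, 0, 1), (PUPIL, TREATMENT_ZONE)):
        if (h, w) != ch.shape:
            ch = resize(ch, (h, w), order=1, preserve_range=True)
        out.append(RegionMask((ch >= threshold).astype(np.uint8), role=role))
    return out[0], out[1]


def augment(
    image,
    masks,
    seed: int,
    max_rot_deg: float = 15.0,
    min_area_frac: float = 0.85,
    noise_sd: float = 4.0,
):
    """Seeded rotation + crop-and-resize + image-only Gaussian noise.

    The identical geometric transform is applied to the masks (nearest
    neighbour); with ``max_rot_deg=0, min_area_frac=1, noise_sd=0`` the
    output equals the input exactly.
    """
    img = as_image_array(image)
    if isinstance(masks, np.ndarray) and masks.ndim == 3:
        mstack = (masks > 0).astype(np.uint8)
    else:
        mstack = np.stack([as_mask_array(m) for m in masks])
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]

    angle = float(rng.uniform(-max_rot_deg, max_rot_deg)) if max_rot_deg else 0.0
    if angle != 0.0:
        img = rotate(img.astype(np.float32), angle, order=1, mode="edge",
                     preserve_range=True)
        mstack = np.stack([
            rotate(m.astype(np.float32), angle, order=0, mode="constant",
                   preserve_range=True) for m in mstack
        ])
        mstack = (mstack > 0.5).astype(np.uint8)

    if min_area_frac < 1.0:
        frac = float(rng.uniform(np.sqrt(min_area_frac), 1.0))
        ch, cw = int(round(h * frac)), int(round(w * frac))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        img = img[top : top + ch, left : left + cw]
        mstack = mstack[:, top : top + ch, left : left + cw]
        img = resize(img.astype(np.float32), (h, w), order=1, preserve_range=True)
        mstack = np.stack([
            resize(m, (h, w), order=0, anti_aliasing=False, preserve_range=True)
            for m in mstack
        ])
        mstack = (mstack > 0.5).astype(np.uint8)

    if noise_sd > 0:
        img = img.astype(np.float32) + rng.normal(0.0, noise_sd, img.shape)

    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, mstack.astype(np.uint8)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class SegMetrics:
    """Pixel-count confusion summary for one region."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    iou: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "SegMetrics":
        # conventions for degenerate denominators: an empty truth matched by
        # an empty prediction is a perfect score, not a crash
        if tp + fp == 0:
            precision = 1.0 if fn == 0 else 0.0
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall = 1.0 if fp == 0 else 0.0
        else:
            recall = tp / (tp + fn)
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        iou = 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
        return cls(int(tp), int(fp), int(fn), precision, recall, f1, iou)


def seg_metrics(pred, truth) -> SegMetrics:
    """Precision/recall/F1/IoU from pixelwise TP, FP, FN counts."""
    p = as_mask_array(pred).astype(bool)
    t = as_mask_array(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return SegMetrics.from_counts(tp, fp, fn)


_TABLE_COLS = [
    "pupil_precision", "tz_precision",
    "pupil_recall", "tz_recall",
    "pupil_f1", "tz_f1",
    "pupil_iou", "tz_iou",
]


def evaluate_model(model: _SegModel, dataset, threshold: float = 0.5,
                   input_size: int | None = None) -> pd.DataFrame:
    """Per-sample metrics table for both regions (one row per sample)."""
    rows = []
    for sample in dataset:
        img, masks = _sample_xy(sample)
        pup, tz = predict_masks(model, img, threshold=threshold, input_size=input_size)
        mp = seg_metrics(pup, masks[0])
        mt = seg_metrics(tz, masks[1])
        rows.append({
            "pupil_precision": mp.precision, "tz_precision": mt.precision,
            "pupil_recall": mp.recall, "tz_recall": mt.recall,
            "pupil_f1": mp.f1, "tz_f1": mt.f1,
            "pupil_iou": mp.iou, "tz_iou": mt.iou,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Disjoint k-fold partition of range(n) after a seeded shuffle."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, k)


def kfold_evaluate(
    dataset,
    k: int = 10,
    model_cfg: SegModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    repeated_random: bool = False,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """k-fold cross-validation: each fold validates once, the rest train.

    Returns a table with one row per fold (index 1..k) and a final ``mean``
    row; columns interleave pupil/treatment-zone precision, recall, F1 and
    IoU.  Fold metrics micro-average pixel counts over the fold's validation
    samples.  With ``repeated_random=True`` the folds are independent random
    80/20-style splits of size n/k instead of a disjoint partition.
    """
    n = len(dataset)
    model_cfg = model_cfg or SegModelConfig(arch="unet", base_width=8)
    train_cfg = train_cfg or TrainConfig(batch_size=min(8, n), epochs=5,
                                         input_size_px=64)
    folds = kfold_split(n, k, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed + 1)
    rows = []
    for f, val_idx in enumerate(folds):
        if repeated_random:
            val_idx = rng.choice(n, size=len(val_idx), replace=False)
        val_set = set(int(i) for i in val_idx)
        train_samples = [dataset[i] for i in range(n) if i not in val_set]
        val_samples = [dataset[i] for i in sorted(val_set)]
        model = build_model(model_cfg, seed=train_cfg.seed + f)
        train(train_samples, model, train_cfg)
        counts = {PUPIL: np.zeros(3, dtype=np.int64),
                  TREATMENT_ZONE: np.zeros(3, dtype=np.int64)}
        for sample in val_samples:
            img, masks = _sample_xy(sample)
            pup, tz = predict_masks(model, img, threshold=threshold)
            for role, pred, truth in ((PUPIL, pup, masks[0]),
                                      (TREATMENT_ZONE, tz, masks[1])):
                m = seg_metrics(pred, truth)
                counts[role] += np.array([m.tp, m.fp, m.fn])
        mp = SegMetrics.from_counts(*counts[PUPIL])
        mt = SegMetrics.from_counts(*counts[TREATMENT_ZONE])
        rows.append({
            "pupil_precision": mp.precision, "tz_precision": mt.precision,
            "pupil_recall": mp.recall, "tz_recall": mt.recall,
            "pupil_f1": mp.f1, "tz_f1": mt.f1,
            "pupil_iou": mp.iou, "tz_iou": mt.iou,
        })
        log.info("fold %d/%d pupil F1 %.4f tz F1 %.4f", f + 1, k, mp.f1, mt.f1)
    df = pd.DataFrame(rows, columns=_TABLE_COLS, index=range(1, k + 1))
    df.loc["mean"] = df.mean()
    return df
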