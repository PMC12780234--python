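"""Segmentation losses, ensembling and a desk-scale trainable backbone.

The training objective combines a focal loss and a soft-Dice loss in a 1:1
ratio; the cyst model additionally uses a boundary loss that weights
predicted foreground probability by the signed distance (mm) to the true
boundary.  Final predictions are the voxel-wise ensemble mean of several
members differing only in their random initialization.

The backbone here is deliberately small: a voxel-wise softmax classifier
over multi-scale image features (intensity, two Gaussian scales, gradient
magnitude, normalized coordinates) trained by full-batch gradient descent on
the combined loss, with analytic gradients.  It is pluggable — anything with
a ``predict_proba(volume) -> (C, *shape)`` method and a ``classes`` tuple
works for ensembling, sliding-window inference and evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .phantom import PhantomSample
from .volume_io import Volume

__all__ = [
    "LossConfig",
    "SEG_CLASSES",
    "one_hot",
    "dice_loss",
    "focal_loss",
    "boundary_loss",
    "combined_loss",
    "combined_loss_grad",
    "ensemble_predict",
    "ToySegmenter",
    "train_toy_segmenter",
    "organ_training_target",
    "DivergenceError",
]

_EPS = 1e-7

#: Class layout of the organ/plaque model (ovaries merged).
SEG_CLASSES: tuple[str, ...] = ("background", "uterus", "bladder", "rectum", "ovary", "plaque")


class DivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


@dataclass(frozen=True)
class LossConfig:
    """Loss weighting: focal and Dice 1:1 by default, optional boundary term."""

    focal_gamma: float = 2.0
    focal_weight: float = 1.0
    dice_weight: float = 1.0
    use_boundary: bool = False
    boundary_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.focal_weight <= 0 or self.dice_weight <= 0:
            raise ValueError("loss ratio components must be > 0")


def one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(C, *shape) one-hot encoding of an integer label array."""
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError("target labels out of range")
    return np.moveaxis(np.eye(n_classes, dtype=np.float32)[target], -1, 0)


def _check_pred(pred: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if pred.ndim != target.ndim + 1 or pred.shape[1:] != target.shape:
        raise ValueError(f"prediction {pred.shape} does not align with target {target.shape}")
    return pred, target


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = _EPS) -> float:
    """1 - soft Dice, averaged over foreground classes.

    Perfect one-hot prediction gives 0; fully disjoint foreground gives 1.
    The epsilon keeps classes absent from both prediction and target neutral.
    """
    pred, target = _check_pred(pred, target)
    t = one_hot(target, pred.shape[0])
    axes = tuple(range(1, pred.ndim))
    inter = (pred * t).sum(axis=axes)
    sums = pred.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + eps) / (sums + eps)
    return float(1.0 - dice[1:].mean())


def focal_loss(pred: np.ndarray, target: np.ndarray, gamma: float = 2.0) -> float:
    """Mean over voxels of ``-(1 - p_t)^gamma * log(p_t)``.

    At gamma = 0 this is the cross-entropy.  Probabilities are clipped to
    [1e-7, 1 - 1e-7].
    """
    pred, target = _check_pred(pred, target)
    p_t = np.clip(np.take_along_axis(pred, target[None], axis=0)[0], _EPS, 1 - _EPS)
    return float(np.mean(-((1 - p_t) ** gamma) * np.log(p_t)))


def _signed_distance(fg: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Signed distance map in mm: negative inside the target, positive outside."""
    outside = ndimage.distance_transform_edt(~fg, sampling=spacing)
    inside = ndimage.distance_transform_edt(fg, sampling=spacing)
    return outside - inside


def boundary_loss(
    pred: np.ndarray, target: np.ndarray, spacing: Sequence[float]
) -> float:
    """Signed-distance-weighted foreground probability, averaged over classes.

    For each foreground class, the mean over voxels of the class probability
    times the signed distance (mm) to the true class boundary.  Placing mass
    inside the target lowers the loss (negative distances); mass outside
    raises it.  An empty target is defined as 0 with a warning.
    """
    pred, target = _check_pred(pred, target)
    n_classes = pred.shape[0]
    terms = []
    for c in range(1, n_classes):
        fg = target == c
        if not fg.any():
            continue
        terms.append(float(np.mean(_signed_distance(fg, spacing) * pred[c])))
    if not terms:
        warnings.warn("boundary loss of an empty target is defined as 0", stacklevel=2)
        return 0.0
    return float(np.mean(terms))


def combined_loss(
    pred: np.ndarray,
    target: np.ndarray,
    cfg: LossConfig = LossConfig(),
    spacing: Sequence[float] | None = None,
) -> float:
    """``focal_weight * focal + dice_weight * dice (+ boundary_weight * boundary)``."""
    total = cfg.focal_weight * focal_loss(pred, target, cfg.focal_gamma)
    total += cfg.dice_weight * dice_loss(pred, target)
    if cfg.use_boundary:
        if spacing is None:
            raise ValueError("boundary loss requires voxel spacing")
        total += cfg.boundary_weight * boundary_loss(pred, target, spacing)
    return float(total)


def combined_loss_grad(
    logits: np.ndarray,
    target: np.ndarray,
    cfg: LossConfig = LossConfig(),
    spacing: Sequence[float] | None = None,
) -> tuple[float, np.ndarray]:
    """Combined loss and its analytic gradient with respect to the logits.

    Gradients of each term are taken with respect to the softmax
    probabilities and chained through the softmax Jacobian.
    """
    logits = np.asarray(logits, dtype=np.float64)
    with np.errstate(invalid="ignore", over="ignore"):
        z = logits - logits.max(axis=0, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=0, keepdims=True)
    n_classes = p.shape[0]
    n_vox = int(np.prod(target.shape))
    t = one_hot(target, n_classes).astype(np.float64)
    g = np.zeros_like(p)  # dL/dp

    # Focal term.
    p_t = np.clip((p * t).sum(axis=0), _EPS, 1 - _EPS)
    focal = float(np.mean(-((1 - p_t) ** cfg.focal_gamma) * np.log(p_t)))
    gamma = cfg.focal_gamma
    dfdp = (gamma * (1 - p_t) ** (gamma - 1) * np.log(p_t) if gamma > 0 else 0.0) - (
        (1 - p_t) ** gamma
    ) / p_t
    g += cfg.focal_weight * t * (dfdp / n_vox)[None]

    # Dice term.
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    sums = p.sum(axis=axes) + t.sum(axis=axes)
    dice_c = (2 * inter + _EPS) / (sums + _EPS)
    dice = float(1.0 - dice_c[1:].mean())
    k = n_classes - 1
    for c in range(1, n_classes):
        num = 2 * t[c] * (sums[c] + _EPS) - (2 * inter[c] + _EPS)
        g[c] += cfg.dice_weight * (-(1.0 / k) * num / (sums[c] + _EPS) ** 2)

    total = cfg.focal_weight * focal + cfg.dice_weight * dice

    if cfg.use_boundary:
        if spacing is None:
            raise ValueError("boundary loss requires voxel spacing")
        terms = []
        present = [c for c in range(1, n_classes) if (target == c).any()]
        for c in present:
            phi = _signed_distance(target == c, spacing)
            terms.append(float(np.mean(phi * p[c])))
            g[c] += cfg.boundary_weight * phi / (n_vox * len(present))
        if terms:
            total += cfg.boundary_weight * float(np.mean(terms))

    # Chain through softmax: dL/dz_c = p_c * (g_c - sum_k g_k p_k).
    dz = p * (g - (g * p).sum(axis=0, keepdims=True))
    return float(total), dz


def ensemble_predict(models: Sequence, v: Volume) -> np.ndarray:
    """Voxel-wise arithmetic mean of member probabilities; argmax is the mask."""
    if len(models) == 0:
        raise ValueError("ensemble needs at least one model")
    classes = getattr(models[0], "classes", None)
    out: np.ndarray | None = None
    for m in models:
        if getattr(m, "classes", None) != classes:
            raise ValueError("ensemble members must share a class set")
        probs = np.asarray(m.predict_proba(v), dtype=np.float64)
        out = probs if out is None else out + probs
    return out / len(models)


def organ_training_target(sample: PhantomSample) -> np.ndarray:
    """Remap a phantom organ mask to the model class layout (ovaries merged)."""
    data = sample.organ_mask.data
    target = np.zeros(data.shape, dtype=np.int64)
    target[data == sample.organ_mask.labels["uterus"]] = 1
    target[data == sample.organ_mask.labels["bladder"]] = 2
    target[data == sample.organ_mask.labels["rectum"]] = 3
    target[data == sample.organ_mask.labels["ovary_left"]] = 4
    target[data == sample.organ_mask.labels["ovary_right"]] = 4
    target[data == sample.organ_mask.labels["plaque"]] = 5
    return target


def _features(data: np.ndarray) -> np.ndarray:
    """(F, N) per-voxel feature matrix: intensity at 3 scales, gradient, coords."""
    data = np.asarray(data, dtype=np.float64)
    g1 = ndimage.gaussian_filter(data, 1.0)
    g3 = ndimage.gaussian_filter(data, (3.0, 3.0, 1.0))
    grad = np.sqrt(sum(np.square(np.gradient(g1, axis=a)) for a in range(3)))
    coords = [
        (np.arange(n) / max(n - 1, 1)).reshape([-1 if a == i else 1 for i in range(3)])
        * np.ones_like(data)
        for a, n in enumerate(data.shape)
    ]
    feats = [np.ones_like(data), data, g1, g3, grad] + coords
    return np.stack([f.ravel() for f in feats], axis=0)


@dataclass
class ToySegmenter:
    """Voxel-wise softmax segmenter over fixed multi-scale features."""

    weights: np.ndarray  # (C, F)
    classes: tuple[str, ...] = SEG_CLASSES
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    def logits(self, data: np.ndarray) -> np.ndarray:
        phi = _features(data)
        return (self.weights @ phi).reshape((self.n_classes,) + data.shape)

    def predict_proba(self, v: Volume | np.ndarray) -> np.ndarray:
        data = v.data if isinstance(v, Volume) else np.asarray(v)
        z = self.logits(data)
        z -= z.max(axis=0, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=0, keepdims=True)

    def patch_predictor(self):
        """Adapter for :func:`pelvamp.volume_io.sliding_window_predict`."""
        return lambda patch: self.predict_proba(patch)


def train_toy_segmenter(
    cohort: Sequence[PhantomSample],
    cfg: LossConfig = LossConfig(),
    epochs: int = 40,
    seed: int = 0,
    lr: float = 0.5,
) -> ToySegmenter:
    """Train the voxel-softmax segmenter on phantom T2 volumes.

    One Adam step per sample per epoch on the combined loss; the per-epoch
    mean training loss is recorded in ``loss_history``.  Fully deterministic
    for a fixed seed.  Raises :class:`DivergenceError` on a non-finite loss.
    """
    if len(cohort) < 1:
        raise ValueError("cohort must not be empty")
    if epochs == 0:
        warnings.warn("epochs=0: returning an untrained segmenter", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_feat = _features(np.zeros((2, 2, 2))).shape[0]
    model = ToySegmenter(rng.normal(0.0, 0.01, size=(len(SEG_CLASSES), n_feat)))

    pairs = [(np.asarray(s.t2_volume.data, np.float64), organ_training_target(s)) for s in cohort]
    spacing = cohort[0].t2_volume.spacing_mm
    feats = [_features(d) for d, _ in pairs]

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m1 = np.zeros_like(model.weights)
    m2 = np.zeros_like(model.weights)
    step = 0
    for _ in range(epochs):
        losses = []
        for (data, target), phi in zip(pairs, feats):
            logits = (model.weights @ phi).reshape((len(SEG_CLASSES),) + data.shape)
            loss, dz = combined_loss_grad(logits, target, cfg, spacing)
            if not np.isfinite(loss):
                raise DivergenceError("training loss is not finite; lower the learning rate")
            losses.append(loss)
            grad_w = dz.reshape(len(SEG_CLASSES), -1) @ phi.T
            step += 1
            m1 = beta1 * m1 + (1 - beta1) * grad_w
            m2 = beta2 * m2 + (1 - beta2) * grad_w**2
            mhat = m1 / (1 - beta1**step)
            vhat = m2 / (1 - beta2**step)
            model.weights -= lr * mhat / (np.sqrt(vhat) + eps)
        model.loss_history.append(float(np.mean(losses)))
    return model
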