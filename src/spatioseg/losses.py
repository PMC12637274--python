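"""Composite training loss: soft Dice + categorical cross-entropy.

Both terms operate on per-pixel class probabilities against one-hot targets.
The Dice term rewards spatial overlap per class; the cross-entropy term
rewards per-pixel classification confidence.  Every function accepts either
plain ``ndarray`` inputs (returning a float) or autodiff Tensors (returning a
Tensor so gradients flow), which keeps a single formula serving both the
evaluation contract and the training loop.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "dice_loss",
    "categorical_cross_entropy",
    "composite_loss",
    "one_hot",
    "CCE_CLIP_EPS",
    "DICE_SMOOTH",
]

CCE_CLIP_EPS = 1e-7
DICE_SMOOTH = 1.0


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(..., H, W) integer labels -> (..., H, W, C) one-hot float array."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(f"labels outside [0, {num_classes})")
    return np.eye(num_classes)[labels]


def _check_shapes(probs, onehot):
    if tuple(probs.shape) != tuple(np.shape(onehot)):
        raise ValueError(f"probs shape {probs.shape} != targets shape {np.shape(onehot)}")


def dice_loss(probs, onehot, smooth: float = DICE_SMOOTH):
    """Soft Dice loss, mean over classes.

    Per class c: ``1 - (2*sum(p*g) + s) / (sum(p) + sum(g) + s)`` with sums
    over batch and pixels.  Smoothing ``s`` stabilizes empty classes: a class
    absent from both prediction and truth has a term of exactly 0.
    """
    is_tensor = isinstance(probs, Tensor)
    probs_t = ad.as_tensor(probs)
    _check_shapes(probs_t, onehot)
    g = np.asarray(onehot, dtype=np.float64)
    axes = tuple(range(probs_t.ndim - 1))
    inter = (probs_t * g).sum(axis=axes)  # (C,)
    denom = probs_t.sum(axis=axes) + g.sum(axis=axes)
    dice = (inter * 2.0 + smooth) * ad.power(denom + smooth, -1.0)
    loss = (1.0 - dice).mean()
    return loss if is_tensor else loss.item()


def categorical_cross_entropy(probs, onehot, clip_eps: float = CCE_CLIP_EPS):
    """Mean over pixels of ``-sum_c g * log(clip(p))``."""
    is_tensor = isinstance(probs, Tensor)
    probs_t = ad.as_tensor(probs)
    _check_shapes(probs_t, onehot)
    g = np.asarray(onehot, dtype=np.float64)
    p = ad.clip(probs_t, clip_eps, 1.0 - clip_eps)
    per_pixel = (ad.log(p) * g).sum(axis=-1) * -1.0
    loss = per_pixel.mean()
    return loss if is_tensor else loss.item()


def composite_loss(probs, onehot, dice_weight: float = 1.0, cce_weight: float = 1.0):
    """Weighted sum of Dice and cross-entropy; default equal weights."""
    if dice_weight < 0 or cce_weight < 0:
        raise ValueError("loss weights must be non-negative")
    is_tensor = isinstance(probs, Tensor)
    loss = dice_loss(probs, onehot) * dice_weight + categorical_cross_entropy(
        probs, onehot
    ) * cce_weight
    return loss if is_tensor else float(loss.item() if isinstance(loss, Tensor) else loss)
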