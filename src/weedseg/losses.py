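"""Compound Dice + cross-entropy training objective.

The Dice loss measures soft region overlap per class over all pixels of the
batch and is averaged over classes; the cross-entropy term is the pixel-mean
negative log-probability of the true class.  The compound loss mixes them
with fixed weights 0.8 (Dice) and 0.2 (cross-entropy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["LossConfig", "dice_loss", "cross_entropy_loss", "compound_loss",
           "one_hot"]


@dataclass(frozen=True)
class LossConfig:
    dice_weight: float = 0.8
    ce_weight: float = 0.2
    smooth: float = 1e-6

    def __post_init__(self):
        if self.dice_weight < 0 or self.ce_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.smooth < 0:
            raise ValueError("smooth must be non-negative")


def one_hot(target: np.ndarray, num_classes: int) -> np.ndarray:
    """(B, H, W) integer labels -> (B, K, H, W) one-hot float array."""
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= num_classes:
        raise ValueError(
            f"labels must lie in [0, {num_classes}), got "
            f"[{target.min()}, {target.max()}]")
    eye = np.eye(num_classes)
    return np.moveaxis(eye[target], -1, 1)


def _check_shapes(probs: Tensor, target: np.ndarray) -> None:
    b, k, h, w = probs.shape
    if np.asarray(target).shape != (b, h, w):
        raise ValueError(
            f"target shape {np.asarray(target).shape} does not match "
            f"probabilities {(b, h, w)}")


def dice_loss(probs: Tensor, target: np.ndarray,
              smooth: float = 1e-6) -> Tensor:
    """Soft Dice loss: 1 - 2*overlap / (mass_p + mass_g), class-averaged.

    ``probs`` holds per-pixel class probabilities (B, K, H, W); ``target`` is
    the integer label grid (B, H, W).  The per-class statistic pools all
    B*H*W pixels; ``smooth`` guards the denominator when a class is absent
    from both prediction and truth.
    """
    _check_shapes(probs, target)
    k = probs.shape[1]
    g = Tensor(one_hot(target, k))
    inter = (probs * g).sum(axis=(0, 2, 3))
    masses = (probs ** 2.0).sum(axis=(0, 2, 3)) + (g ** 2.0).sum(axis=(0, 2, 3))
    dice = (2.0 * inter) / (masses + smooth)
    return (1.0 - dice).mean()


def cross_entropy_loss(probs: Tensor, target: np.ndarray,
                       eps: float = 1e-12) -> Tensor:
    """Pixel-mean negative log-probability of the true class."""
    _check_shapes(probs, target)
    k = probs.shape[1]
    g = Tensor(one_hot(target, k))
    clamped = probs + eps  # guards log(0) where the prediction has no mass
    return -(g * clamped.log()).sum(axis=1).mean()


def compound_loss(logits: Tensor, target: np.ndarray,
                  cfg: LossConfig = LossConfig()) -> Tensor:
    """Weighted Dice + cross-entropy on raw logits (softmax applied here).

    The cross-entropy term uses the numerically stable log-softmax rather
    than the probabilities' logarithm; the two agree to rounding.
    """
    _check_shapes(logits, target)
    k = logits.shape[1]
    probs = logits.softmax(axis=1)
    dice = dice_loss(probs, target, cfg.smooth)
    g = Tensor(one_hot(target, k))
    ce = -(g * logits.log_softmax(axis=1)).sum(axis=1).mean()
    return cfg.dice_weight * dice + cfg.ce_weight * ce
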