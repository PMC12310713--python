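"""Training losses: binary cross-entropy, soft Dice, and their weighted sum.

All three take softmax probabilities in (N, num_classes, H, W) layout and a
label batch in {0, 1}; ``p`` denotes the positive-class (label 1) plane.
Cross-entropy averages over every pixel of the batch; Dice is computed per
image and averaged.  The analytic gradients returned by ``*_grad`` are with
respect to the probability array (only the positive-class plane is touched,
matching the losses' dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # log clamp


@dataclass(frozen=True)
class LossWeights:
    w1: float = 0.8  # Dice weight
    w2: float = 0.2  # cross-entropy weight

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError(f"loss weights must be nonnegative, got ({self.w1}, {self.w2})")
        if self.w1 + self.w2 <= 0:
            raise ValueError("at least one loss weight must be positive")


def _check(probabilities: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(truth)
    if p.ndim != 4:
        raise ValueError(f"probabilities must be (N, K, H, W), got shape {p.shape}")
    if y.shape != (p.shape[0],) + p.shape[2:]:
        raise ValueError(f"truth shape {y.shape} does not match probabilities {p.shape}")
    return p[:, 1], y.astype(np.float64)


def ce_loss(probabilities: np.ndarray, truth: np.ndarray) -> float:
    """Mean over pixels of -[y log p + (1-y) log(1-p)], logs clamped at 1e-7."""
    p, y = _check(probabilities, truth)
    pc = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1.0 - pc)))


def ce_grad(probabilities: np.ndarray, truth: np.ndarray) -> np.ndarray:
    p, y = _check(probabilities, truth)
    pc = np.clip(p, EPS, 1.0 - EPS)
    g = np.zeros_like(np.asarray(probabilities, dtype=np.float64))
    g[:, 1] = (-y / pc + (1 - y) / (1.0 - pc)) / p.size
    return g


def dice_loss(probabilities: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 - (2 sum(p*y) + s) / (sum(p) + sum(y) + s), per image."""
    p, y = _check(probabilities, truth)
    num = 2.0 * (p * y).sum(axis=(1, 2)) + smooth
    den = p.sum(axis=(1, 2)) + y.sum(axis=(1, 2)) + smooth
    per_image = np.where(den > 0, 1.0 - num / np.maximum(den, EPS), 0.0)
    return float(per_image.mean())


def dice_grad(probabilities: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    p, y = _check(probabilities, truth)
    num = 2.0 * (p * y).sum(axis=(1, 2)) + smooth
    den = p.sum(axis=(1, 2)) + y.sum(axis=(1, 2)) + smooth
    g = np.zeros_like(np.asarray(probabilities, dtype=np.float64))
    n = p.shape[0]
    g[:, 1] = -(2.0 * y * den[:, None, None] - num[:, None, None]) / (den ** 2)[:, None, None] / n
    return g


def joint_loss(probabilities: np.ndarray, truth: np.ndarray,
               weights: LossWeights = LossWeights(), smooth: float = 1.0) -> float:
    """w1 * Dice loss + w2 * cross-entropy loss (defaults 0.8 / 0.2)."""
    return (weights.w1 * dice_loss(probabilities, truth, smooth)
            + weights.w2 * ce_loss(probabilities, truth))


def joint_grad(probabilities: np.ndarray, truth: np.ndarray,
               weights: LossWeights = LossWeights(), smooth: float = 1.0) -> np.ndarray:
    return (weights.w1 * dice_grad(probabilities, truth, smooth)
            + weights.w2 * ce_grad(probabilities, truth))
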