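"""Composite segmentation loss: binary cross entropy plus Dice loss.

With ground truth :math:`p_i \\in \\{0, 1\\}` and predicted lesion
probability :math:`q_i \\in [0, 1]` over :math:`N` voxels,

.. math::

    L_{BCE}  &= -\\tfrac{1}{N} \\sum_i p_i \\log q_i
                + (1 - p_i) \\log(1 - q_i), \\\\
    L_{Dice} &= 1 - \\frac{2 \\sum_i p_i q_i + s}
                         {\\sum_i p_i^2 + \\sum_i q_i^2 + s}, \\\\
    L_{total} &= L_{BCE} + L_{Dice}.

Cross entropy penalizes every voxel independently; the Dice term
directly targets the overlap score used at evaluation time.  The
smoothing constant ``s`` guards the Dice denominator (whose gradient is
unstable when tiny) and makes the empty-vs-empty case a perfect score.
Probabilities entering the logarithms are clipped away from {0, 1} so
saturated outputs keep a finite loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lesionseg.errors import InvalidConfigError

__all__ = ["LossValue", "bce_loss", "dice_loss", "total_loss", "loss_and_logit_grad"]

DEFAULT_SMOOTHING = 1e-6  # Dice denominator guard
CLIP_EPS = 1e-7  # probability clipping for the log terms


@dataclass
class LossValue:
    """Composite loss with its components (``total = bce + dice``)."""

    total: float
    bce: float
    dice: float


def _check_shapes(truth: np.ndarray, prob: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=np.float64)
    prob = np.asarray(prob, dtype=np.float64)
    if truth.shape != prob.shape:
        raise InvalidConfigError(f"shape mismatch: truth {truth.shape} vs prob {prob.shape}")
    return truth, prob


def bce_loss(truth, prob, clip: float = CLIP_EPS) -> float:
    """Mean binary cross entropy between a 0/1 field and a probability field."""
    truth, prob = _check_shapes(truth, prob)
    q = np.clip(prob, clip, 1.0 - clip)
    return float(-(truth * np.log(q) + (1.0 - truth) * np.log(1.0 - q)).mean())


def dice_loss(truth, prob, smoothing: float = DEFAULT_SMOOTHING) -> float:
    """Soft Dice loss ``1 - (2 sum(pq) + s) / (sum(p^2) + sum(q^2) + s)``."""
    truth, prob = _check_shapes(truth, prob)
    num = 2.0 * (truth * prob).sum() + smoothing
    den = (truth**2).sum() + (prob**2).sum() + smoothing
    return float(1.0 - num / den)


def total_loss(truth, prob, smoothing: float = DEFAULT_SMOOTHING, clip: float = CLIP_EPS) -> LossValue:
    """Cross entropy plus Dice loss, with the components."""
    b = bce_loss(truth, prob, clip)
    d = dice_loss(truth, prob, smoothing)
    return LossValue(total=b + d, bce=b, dice=d)


def loss_and_logit_grad(
    truth: np.ndarray,
    logits: np.ndarray,
    smoothing: float = DEFAULT_SMOOTHING,
    clip: float = CLIP_EPS,
) -> tuple[LossValue, np.ndarray]:
    """Composite loss and its gradient w.r.t. the two-channel logits.

    ``logits`` is the network's pre-softmax field ``(2, D, H, W)``
    (channel 0 = non-lesion, channel 1 = lesion).  The softmax of a
    two-class field reduces to ``q = sigmoid(z1 - z0)``; the chain rule
    through that sigmoid gives the logit gradient analytically.
    """
    truth = np.asarray(truth, dtype=np.float64)
    if logits.shape[0] != 2 or logits.shape[1:] != truth.shape:
        raise InvalidConfigError(
            f"expected logits (2, *{truth.shape}), got {logits.shape}"
        )
    z = logits.astype(np.float64)
    margin = z[1] - z[0]
    q = 1.0 / (1.0 + np.exp(-margin))

    value = total_loss(truth, q, smoothing=smoothing, clip=clip)

    n = truth.size
    qc = np.clip(q, clip, 1.0 - clip)
    # d BCE / d q
    g_bce = -(truth / qc - (1.0 - truth) / (1.0 - qc)) / n
    # d Dice / d q
    num = 2.0 * (truth * q).sum() + smoothing
    den = (truth**2).sum() + (q**2).sum() + smoothing
    g_dice = -(2.0 * truth * den - num * 2.0 * q) / den**2
    g_q = g_bce + g_dice
    g_margin = g_q * q * (1.0 - q)
    grad = np.stack([-g_margin, g_margin]).astype(np.float32)
    return value, grad
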