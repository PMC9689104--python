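"""Softmax head and the weighted two-class Dice loss used for training.

The loss for one image is

    L = sum_e C_e * (1 - 2 * sum(L_e * S_e) / (sum(L_e) + sum(S_e) + eps))

where e runs over {background, foreground}, L_e is the one-hot ground
truth, S_e the softmax probability map and C_e the class weight.  A small
epsilon keeps the ratio defined when a class is absent from both maps.
"""

from __future__ import annotations

import numpy as np

DICE_EPS = 1e-6


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of (B, C, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=1, keepdims=True)).astype(np.float32)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """(B, H, W) integer labels -> (B, C, H, W) one-hot float grid."""
    B, H, W = labels.shape
    out = np.zeros((B, n_classes, H, W), dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def weighted_dice_loss(prob: np.ndarray, target_onehot: np.ndarray,
                       weights=(0.5, 0.5), eps: float = DICE_EPS,
                       return_grad: bool = False):
    """Mean per-image weighted Dice loss; optionally d(loss)/d(prob).

    ``prob`` and ``target_onehot`` are (B, C, H, W); sums run over all
    H x W pixels of each image, and the batch is averaged.
    """
    prob = np.asarray(prob, dtype=np.float32)
    tgt = np.asarray(target_onehot, dtype=np.float32)
    if prob.shape != tgt.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {tgt.shape}")
    B, C = prob.shape[:2]
    weights = np.asarray(weights, dtype=np.float64)
    inter = (prob * tgt).sum(axis=(2, 3))          # (B, C)
    denom = prob.sum(axis=(2, 3)) + tgt.sum(axis=(2, 3)) + eps
    dice = 2.0 * inter / denom
    loss = float((weights[None, :] * (1.0 - dice)).sum(axis=1).mean())
    if not return_grad:
        return loss
    # d/dS_e of (1 - 2 I_e / D_e) = -2 L_e / D_e + 2 I_e / D_e^2
    g = (-2.0 * tgt / denom[:, :, None, None]
         + 2.0 * inter[:, :, None, None] / (denom ** 2)[:, :, None, None])
    g *= weights[None, :, None, None] / B
    return loss, g.astype(np.float32)


def softmax_dice_loss_grad(logits: np.ndarray, target_onehot: np.ndarray,
                           weights=(0.5, 0.5)):
    """Loss value and gradient w.r.t. the pre-softmax logits."""
    prob = softmax_channels(logits)
    loss, dprob = weighted_dice_loss(prob, target_onehot, weights, return_grad=True)
    inner = (dprob * prob).sum(axis=1, keepdims=True)
    dlogits = prob * (dprob - inner)
    return loss, dlogits.astype(np.float32), prob
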