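"""Dice overlap score and the soft Dice training objective.

Dice = 2|A n B| / (|A| + |B|) between the reference mask A and the predicted
mask B; the soft variant substitutes per-pixel probabilities for B so the
loss 1 - Dice is differentiable.  A small smoothing term makes the
empty-vs-empty case evaluate to 1 (loss 0).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

EPS = 1e-6


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray,
                     eps: float = EPS) -> float:
    """Hard Dice overlap between two binary masks of equal shape."""
    a = np.asarray(pred_mask)
    b = np.asarray(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = (a != 0)
    b = (b != 0)
    inter = np.logical_and(a, b).sum(dtype=np.float64)
    return float((2.0 * inter + eps) / (a.sum(dtype=np.float64)
                                        + b.sum(dtype=np.float64) + eps))


def dice_loss(prob: Tensor, true_mask: np.ndarray,
              weight_map: np.ndarray | None = None,
              eps: float = EPS) -> Tensor:
    """1 - soft Dice of a leaf-probability tensor against a binary mask.

    ``prob`` may carry a leading batch axis; the overlap is computed over
    all pixels jointly.  ``weight_map`` optionally reweights pixels (a hook
    for boundary-emphasis schemes); by default all pixels count equally.
    """
    t = np.asarray(true_mask, dtype=np.float32)
    if prob.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {prob.data.shape} vs {t.shape}")
    if weight_map is not None:
        w = np.asarray(weight_map, dtype=np.float32)
        if w.shape != t.shape:
            raise ValueError(f"weight map shape {w.shape} != {t.shape}")
        prob = prob * Tensor(w)
        t = t * w
    inter = (prob * Tensor(t)).sum()
    denom = prob.sum() + float(t.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)
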