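"""Scalar losses with analytic gradients.

Each function returns ``(loss, grad)`` where ``grad`` is the derivative of
the mean loss with respect to the first argument.
"""

from __future__ import annotations

import numpy as np


def bce_with_logits(logits: np.ndarray, target: float | np.ndarray):
    """Binary cross-entropy on raw logits, numerically stable.

    mean over all elements of  max(z,0) - z*t + log(1 + exp(-|z|)).
    """
    z = logits
    t = np.broadcast_to(np.asarray(target, dtype=z.dtype), z.shape)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = (sig - t) / z.size
    return float(loss.mean()), grad


def l1_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    grad = np.sign(diff) / diff.size
    return float(np.abs(diff).mean()), grad.astype(pred.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    grad = 2.0 * diff / diff.size
    return float((diff ** 2).mean()), grad.astype(pred.dtype)
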