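"""Classification losses."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray,
                           return_grad: bool = False):
    """Class-weighted cross-entropy over a batch.

    The batch reduction is the weighted mean: ``sum_i w_{y_i} * nll_i /
    sum_i w_{y_i}``, so the loss scale is invariant to the batch's class
    composition.  With ``return_grad=True`` also returns d(loss)/d(logits).
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels))
    class_weights = np.asarray(class_weights, dtype=np.float64)
    n, k = logits.shape
    if labels.shape[0] != n:
        raise ValueError("logits and labels disagree on batch size")
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError("label out of range")
    if class_weights.shape[0] != k or np.any(class_weights <= 0):
        raise ValueError("need one positive weight per class")

    p = softmax(logits, axis=1)
    w = class_weights[labels]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    loss = float((w * nll).sum() / w.sum())
    if not return_grad:
        return loss
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad
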