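"""Classification losses and softmax utilities."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["softmax_probs", "softmax_cross_entropy"]


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a (N, K) logit array (numerically stabilized)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, sample_weights: np.ndarray | None = None
) -> Tensor:
    """Weighted categorical cross-entropy, fused with softmax.

    ``labels`` are integer class indices; ``sample_weights`` multiply each
    example's loss term (class weighting).  Returns the mean over the batch
    of ``w_i * CE_i``.
    """
    n = logits.data.shape[0]
    if sample_weights is None:
        sample_weights = np.ones(n, dtype=logits.data.dtype)
    p = softmax_probs(logits.data)
    eps = np.finfo(p.dtype).tiny
    ll = -np.log(p[np.arange(n), labels] + eps)
    loss = float(np.mean(sample_weights * ll))

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        grad *= (sample_weights / n)[:, None]
        return (g * grad,)

    return Tensor._node(np.asarray(loss, dtype=p.dtype), (logits,), backward)
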