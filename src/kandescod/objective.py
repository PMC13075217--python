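"""Training objective: mean-absolute noise reconstruction plus a sparsity +
entropy penalty on the spline-path weights.

The regularizer is ``gamma_a * sum|w| + gamma_e * H(p)`` where ``p`` is the
distribution of absolute spline-weight magnitudes normalised by their L1
norm.  Entropy is computed as ``log(S) - sum(|w| log|w|) / S`` with
``S = sum|w|`` (algebraically identical to ``-sum p log p``), which keeps
the equal-unit-weights case exactly ``log n`` and handles ``0 log 0 := 0``.
As printed, the entropy term is *added* to a minimised loss; the
``entropy_sign`` flag allows the opposite (entropy-maximising) reading.

All functions accept NumPy arrays or autograd Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = ["LossWeights", "main_loss", "kan_reg_loss", "total_loss"]

_TINY = 1e-300  # additive guard inside log(); exact for |w| = 0 (0 * log(tiny) term vanishes)


@dataclass(frozen=True)
class LossWeights:
    lambda_kan: float = 0.001
    gamma_a: float = 1.0
    gamma_e: float = 1.0
    entropy_sign: float = 1.0  # +1 follows the printed objective; -1 maximises entropy

    def __post_init__(self):
        if self.lambda_kan < 0 or self.gamma_a < 0 or self.gamma_e < 0:
            raise ValueError("loss coefficients must be non-negative")


def main_loss(eps_pred, eps_true):
    """Mean absolute difference between predicted and injected noise."""
    if isinstance(eps_pred, Tensor) or isinstance(eps_true, Tensor):
        if ag._wrap(eps_pred).shape != ag._wrap(eps_true).shape:
            raise ValueError("shape mismatch")
        return ag.mean(ag.abs_(ag._wrap(eps_pred) - ag._wrap(eps_true)))
    eps_pred = np.asarray(eps_pred, dtype=np.float64)
    eps_true = np.asarray(eps_true, dtype=np.float64)
    if eps_pred.shape != eps_true.shape:
        raise ValueError(f"shape mismatch: {eps_pred.shape} vs {eps_true.shape}")
    return float(np.mean(np.abs(eps_pred - eps_true)))


def kan_reg_loss(spline_weights, weights: LossWeights = LossWeights()):
    """Sparsity + entropy penalty over all spline-path weight entries.

    ``spline_weights`` is an iterable of weight matrices (arrays or
    Tensors).  Returns 0 when every weight is zero.
    """
    tensors = [w for w in spline_weights]
    if not tensors:
        return 0.0
    if any(isinstance(w, Tensor) for w in tensors):
        flat = ag.concat([ag.reshape(ag._wrap(w), (-1,)) for w in tensors])
        a = ag.abs_(flat)
        s = ag.sum_(a)
        if s.data == 0.0:
            return 0.0 * s  # keep the graph alive with a zero contribution
        entropy = ag.log(s) - ag.sum_(a * ag.log(a + _TINY)) / s
        return weights.gamma_a * s + (weights.gamma_e * weights.entropy_sign) * entropy
    a = np.abs(np.concatenate([np.asarray(w, dtype=np.float64).ravel() for w in tensors]))
    if not np.all(np.isfinite(a)):
        raise ValueError("spline weights must be finite")
    s = a.sum()
    if s == 0.0:
        return 0.0
    wlogw = np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0)), 0.0)
    entropy = np.log(s) - wlogw.sum() / s
    return float(weights.gamma_a * s + weights.gamma_e * weights.entropy_sign * entropy)


def total_loss(main, reg, weights: LossWeights = LossWeights()):
    """main + lambda_kan * reg."""
    if weights.lambda_kan == 0.0 and not isinstance(main, Tensor):
        return main
    return main + weights.lambda_kan * reg
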