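"""Noise-level conditioning: positional encoding of the diffusion noise
scale, mapped to per-channel feature-wise affine parameters (gamma, beta)
through either a plain linear layer or a two-path spline ("KAN") layer.

All operations accept parameters stored as NumPy arrays or as autograd
Tensors; with Tensors the computation is differentiable with respect to the
layer weights (the encoding itself is a constant input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .splines import SplineGrid, basis_matrix

__all__ = [
    "NoiseEmbedding", "LinearAffineParams", "KANLayerParams",
    "positional_encode", "encode_batch", "linear_affine", "kan_affine",
    "film_modulate", "init_linear_affine", "init_kan_affine",
]


@dataclass(frozen=True)
class NoiseEmbedding:
    sigma_t: float
    d: int
    lam: float
    z: np.ndarray = field(repr=False)


def positional_encode(sigma_t: float, d: int) -> NoiseEmbedding:
    """Interleaved sin/cos encoding of the noise scale at ``d/2`` frequencies.

    ``z = (sin(s), cos(s), sin(s e^-lam), cos(s e^-lam), ...)`` with
    ``lam = ln(10000) / (d/2)``.
    """
    if d < 2 or d % 2 != 0:
        raise ValueError(f"embedding dimension must be even and >= 2, got {d}")
    if not np.isfinite(sigma_t) or sigma_t < 0:
        raise ValueError(f"sigma_t must be a finite non-negative real, got {sigma_t}")
    z = encode_batch(np.asarray([sigma_t]), d)[0]
    lam = math.log(10000.0) / (d / 2)
    return NoiseEmbedding(float(sigma_t), int(d), lam, z)


def encode_batch(sigmas: np.ndarray, d: int) -> np.ndarray:
    """Vectorised positional encoding: (B,) -> (B, d)."""
    sigmas = np.asarray(sigmas, dtype=np.float64)
    lam = math.log(10000.0) / (d / 2)
    freqs = np.exp(-lam * np.arange(d // 2))
    arg = sigmas[:, None] * freqs[None, :]
    z = np.empty((sigmas.shape[0], d))
    z[:, 0::2] = np.sin(arg)
    z[:, 1::2] = np.cos(arg)
    return z


# ----------------------------------------------------------------------
@dataclass
class LinearAffineParams:
    """Weights of the baseline linear conditioning layer: out = W z + b."""

    W: object  # (2C, d) array or Tensor
    b: object  # (2C,)

    @property
    def n_channels(self) -> int:
        return _shape(self.W)[0] // 2


@dataclass
class KANLayerParams:
    """Two-path spline conditioning layer.

    out = scale_base * (W_base @ act(z)) + scale_spline * (W_spline_eff @ B(z))
    where B(z) concatenates, input by input, the n_basis spline basis values,
    and W_spline_eff optionally carries one standalone multiplier per
    (output, input) pair on the spline path.
    """

    grid: SplineGrid
    W_base: object    # (2C, d)
    W_spline: object  # (2C, d * n_basis)
    spline_scale: object = None  # (2C, d) standalone multipliers, or None
    base_activation: str = "silu"
    scale_base: float = 1.0
    scale_spline: float = 1.0

    @property
    def n_channels(self) -> int:
        return _shape(self.W_base)[0] // 2

    @property
    def standalone_scale_spline(self) -> bool:
        return self.spline_scale is not None


def _shape(x):
    return x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape


def _base_act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "silu":
        return z / (1.0 + np.exp(-z))
    if name == "identity":
        return z
    raise ValueError(f"unknown base activation {name!r}")


def init_linear_affine(rng: np.random.Generator, n_channels: int, d: int,
                       trainable: bool = True) -> LinearAffineParams:
    bound = 1.0 / math.sqrt(d)
    W = rng.uniform(-bound, bound, size=(2 * n_channels, d))
    b = np.zeros(2 * n_channels)
    if trainable:
        return LinearAffineParams(Tensor(W, requires_grad=True), Tensor(b, requires_grad=True))
    return LinearAffineParams(W, b)


def init_kan_affine(rng: np.random.Generator, n_channels: int, d: int, grid: SplineGrid,
                    base_activation: str = "silu", scale_base: float = 1.0,
                    scale_spline: float = 1.0, standalone_scale_spline: bool = True,
                    spline_init_scale: float = 0.01, trainable: bool = True) -> KANLayerParams:
    """Fan-in init for the base path; near-zero spline path so the layer
    starts close to its linear ablation."""
    bound = 1.0 / math.sqrt(d)
    W_base = rng.uniform(-bound, bound, size=(2 * n_channels, d))
    W_spline = rng.uniform(-spline_init_scale, spline_init_scale,
                           size=(2 * n_channels, d * grid.n_basis))
    scale = np.ones((2 * n_channels, d)) if standalone_scale_spline else None
    if trainable:
        W_base = Tensor(W_base, requires_grad=True)
        W_spline = Tensor(W_spline, requires_grad=True)
        if scale is not None:
            scale = Tensor(scale, requires_grad=True)
    return KANLayerParams(grid, W_base, W_spline, scale, base_activation,
                          float(scale_base), float(scale_spline))


# ----------------------------------------------------------------------
def _linear_batch(params: LinearAffineParams, Z: np.ndarray):
    """(B, d) -> (B, 2C); works for array or Tensor weights."""
    d = _shape(params.W)[1]
    if Z.shape[-1] != d:
        raise ValueError(f"embedding length {Z.shape[-1]} != weight columns {d}")
    return Z @ params.W.T + params.b


def _kan_batch(params: KANLayerParams, Z: np.ndarray):
    """(B, d) -> (B, 2C); spline path expands each input through the basis."""
    d = _shape(params.W_base)[1]
    if Z.shape[-1] != d:
        raise ValueError(f"embedding length {Z.shape[-1]} != weight columns {d}")
    Z = np.asarray(Z, dtype=np.float64)
    nb = params.grid.n_basis
    act = _base_act(params.base_activation, Z)
    Bz = basis_matrix(params.grid, Z.ravel()).reshape(Z.shape[0], d * nb)
    W_spline = params.W_spline
    if params.spline_scale is not None:
        if isinstance(W_spline, Tensor) or isinstance(params.spline_scale, Tensor):
            W_spline = W_spline * ag.repeat(ag._wrap(params.spline_scale), nb, axis=1)
        else:
            W_spline = W_spline * np.repeat(params.spline_scale, nb, axis=1)
    base = act @ params.W_base.T
    spline = Bz @ W_spline.T
    return params.scale_base * base + params.scale_spline * spline


def _split_halves(out, n_channels: int):
    gamma = out[..., :n_channels]
    beta = out[..., n_channels:]
    return gamma, beta


def linear_affine(params: LinearAffineParams, z: np.ndarray):
    """Map one embedding vector to (gamma, beta), each of length C."""
    z = np.asarray(z, dtype=np.float64)
    out = _linear_batch(params, z[None, :])
    gamma, beta = _split_halves(out, params.n_channels)
    return gamma[0], beta[0]


def kan_affine(params: KANLayerParams, z: np.ndarray):
    """Map one embedding vector through both paths to (gamma, beta)."""
    z = np.asarray(z, dtype=np.float64)
    out = _kan_batch(params, z[None, :])
    gamma, beta = _split_halves(out, params.n_channels)
    return gamma[0], beta[0]


def film_modulate(h_in, gamma, beta):
    """Per-channel affine modulation: out = (1 + gamma) * h + beta.

    ``h_in`` has shape (C, L) or (B, C, L); gamma/beta have shape (C,) or
    (B, C) and broadcast over the time axis.
    """
    tensor_path = any(isinstance(x, Tensor) for x in (h_in, gamma, beta))
    h_shape = _shape(h_in) if tensor_path else np.asarray(h_in).shape
    g_shape = _shape(gamma) if isinstance(gamma, Tensor) else np.asarray(gamma).shape
    if h_shape[-2] != g_shape[-1]:
        raise ValueError(f"channel mismatch: h has {h_shape[-2]} channels, gamma has {g_shape[-1]}")
    if tensor_path:
        g = ag.reshape(ag._wrap(gamma), g_shape + (1,))
        b = ag.reshape(ag._wrap(beta), g_shape + (1,))
        return (1.0 + g) * ag._wrap(h_in) + b
    h_in = np.asarray(h_in, dtype=np.float64)
    gamma = np.asarray(gamma, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    return (1.0 + gamma)[..., None] * h_in + beta[..., None]
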