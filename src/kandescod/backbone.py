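"""Conditional noise-prediction network for 1-D segments.

A multi-scale residual convolutional encoder/decoder.  The noisy
observation is concatenated with the diffusion state on the channel axis at
the input ("signal-based" conditioning); the noise-level embedding enters
through Bridge modules — a 1x1 channel projection followed by feature-wise
affine modulation whose (gamma, beta) come from either a linear or a spline
("kan") conditioning layer.  Switching linear <-> kan changes only the
Bridge affine parameters; the rest of the network is identical.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .conditioning import (KANLayerParams, LinearAffineParams, _kan_batch,
                           _linear_batch, _split_halves, encode_batch,
                           film_modulate, init_kan_affine, init_linear_affine)
from .splines import build_grid

__all__ = ["DenoiserConfig", "Denoiser", "predict_noise", "save_checkpoint", "load_checkpoint"]


@dataclass
class DenoiserConfig:
    hidden_features: int = 80
    n_levels: int = 3
    blocks_per_level: int = 2
    conditioning_kind: str = "kan"  # {"linear", "kan"}
    embedding_dim: int | None = None  # default 2 * hidden_features
    segment_length: int = 512
    # spline conditioning hyperparameters
    grid_size: int = 5
    spline_order: int = 3
    grid_range: tuple = (-1.0, 1.0)
    base_activation: str = "silu"
    scale_base: float = 1.0
    scale_spline: float = 1.0
    standalone_scale_spline: bool = True

    def __post_init__(self):
        if self.embedding_dim is None:
            self.embedding_dim = 2 * self.hidden_features
        if self.embedding_dim % 2 != 0:
            raise ValueError("embedding_dim must be even")
        if self.conditioning_kind not in ("linear", "kan"):
            raise ValueError(f"unknown conditioning_kind {self.conditioning_kind!r}")
        stride_total = 2 ** (self.n_levels - 1)
        if self.segment_length % stride_total != 0:
            raise ValueError(
                f"segment_length {self.segment_length} not divisible by 2^(n_levels-1)={stride_total}")


def _conv_init(rng, c_out, c_in, k):
    bound = 1.0 / math.sqrt(c_in * k)
    return (Tensor(rng.uniform(-bound, bound, (c_out, c_in, k)), requires_grad=True),
            Tensor(np.zeros(c_out), requires_grad=True))


class Denoiser:
    """epsilon_theta(x_t, sigma_t, x_cond) -> predicted injected noise."""

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        C = config.hidden_features
        d = config.embedding_dim
        p: dict[str, tuple[Tensor, Tensor]] = {}
        p["stem"] = _conv_init(rng, C, 2, 3)
        for lvl in range(config.n_levels):
            for blk in range(config.blocks_per_level):
                p[f"down{lvl}.block{blk}.c1"] = _conv_init(rng, C, C, 3)
                p[f"down{lvl}.block{blk}.c2"] = _conv_init(rng, C, C, 3)
            if lvl < config.n_levels - 1:
                p[f"down{lvl}.pool"] = _conv_init(rng, C, C, 3)
        p["mid.c1"] = _conv_init(rng, C, C, 3)
        p["mid.c2"] = _conv_init(rng, C, C, 3)
        for lvl in range(config.n_levels - 1):
            p[f"up{lvl}.smooth"] = _conv_init(rng, C, C, 3)
            p[f"up{lvl}.proj"] = _conv_init(rng, C, C, 1)
            p[f"up{lvl}.block.c1"] = _conv_init(rng, C, C, 3)
            p[f"up{lvl}.block.c2"] = _conv_init(rng, C, C, 3)
        # zero-initialized head: the untrained network predicts zero noise
        wh = Tensor(np.zeros((1, C, 3)), requires_grad=True)
        bh = Tensor(np.zeros(1), requires_grad=True)
        p["head"] = (wh, bh)
        self.convs = p

        # one Bridge affine module per level: levels 0..n-2 gate the skip
        # connections, the last gates the bottleneck features
        self.bridges = []
        if config.conditioning_kind == "kan":
            grid = build_grid(config.grid_size, config.spline_order, *config.grid_range)
            for _ in range(config.n_levels):
                self.bridges.append(init_kan_affine(
                    rng, C, d, grid,
                    base_activation=config.base_activation,
                    scale_base=config.scale_base, scale_spline=config.scale_spline,
                    standalone_scale_spline=config.standalone_scale_spline))
        else:
            for _ in range(config.n_levels):
                self.bridges.append(init_linear_affine(rng, C, d))

    # -- parameter plumbing -------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        out = {}
        for name, (w, b) in self.convs.items():
            out[f"{name}.w"] = w
            out[f"{name}.b"] = b
        for i, br in enumerate(self.bridges):
            if isinstance(br, KANLayerParams):
                out[f"bridge{i}.W_base"] = br.W_base
                out[f"bridge{i}.W_spline"] = br.W_spline
                if br.spline_scale is not None:
                    out[f"bridge{i}.spline_scale"] = br.spline_scale
            else:
                out[f"bridge{i}.W"] = br.W
                out[f"bridge{i}.b"] = br.b
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def spline_weight_tensors(self) -> list[Tensor]:
        """Spline-path weights (incl. standalone scales) for regularization."""
        out = []
        for br in self.bridges:
            if isinstance(br, KANLayerParams):
                out.append(br.W_spline)
                if br.spline_scale is not None:
                    out.append(br.spline_scale)
        return out

    def num_parameters(self) -> dict[str, int]:
        shared = sum(w.data.size + b.data.size for w, b in self.convs.values())
        bridge = sum(t.data.size for n, t in self.named_parameters().items()
                     if n.startswith("bridge"))
        return {"shared": shared, "bridge": bridge, "total": shared + bridge}

    def zero_(self) -> None:
        for t in self.parameters():
            t.data[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)}")
        for k, t in params.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {t.data.shape} vs {state[k].shape}")
            t.data[...] = state[k]

    # -- forward -------------------------------------------------------
    def _conv(self, name, h, stride=1):
        w, b = self.convs[name]
        pad = (w.data.shape[2] - 1) // 2
        return ag.conv1d(h, w, b, stride=stride, padding=pad)

    def _resblock(self, prefix, h):
        y = self._conv(f"{prefix}.c1", ag.silu(h))
        y = self._conv(f"{prefix}.c2", ag.silu(y))
        return h + y

    def _bridge_gammabeta(self, i, Z):
        br = self.bridges[i]
        if isinstance(br, KANLayerParams):
            out = _kan_batch(br, Z)
        else:
            out = _linear_batch(br, Z)
        return _split_halves(out, self.config.hidden_features)

    def forward(self, x_t: np.ndarray, sigma_t, x_cond: np.ndarray) -> Tensor:
        cfg = self.config
        x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
        x_cond = np.atleast_2d(np.asarray(x_cond, dtype=np.float64))
        if x_t.shape != x_cond.shape:
            raise ValueError(f"state/conditioning shape mismatch: {x_t.shape} vs {x_cond.shape}")
        if x_t.shape[1] != cfg.segment_length:
            raise ValueError(f"expected segments of length {cfg.segment_length}, got {x_t.shape[1]}")
        if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(x_cond))):
            raise ValueError("non-finite input")
        B = x_t.shape[0]
        sig = np.broadcast_to(np.asarray(sigma_t, dtype=np.float64), (B,))
        Z = encode_batch(sig, cfg.embedding_dim)

        x = np.stack([x_t, x_cond], axis=1)  # (B, 2, L)
        h = self._conv("stem", Tensor(x))
        skips = []
        for lvl in range(cfg.n_levels):
            for blk in range(cfg.blocks_per_level):
                h = self._resblock(f"down{lvl}.block{blk}", h)
            skips.append(h)
            if lvl < cfg.n_levels - 1:
                h = self._conv(f"down{lvl}.pool", h, stride=2)
        gamma, beta = self._bridge_gammabeta(cfg.n_levels - 1, Z)
        h = film_modulate(h, gamma, beta)
        h = self._resblock("mid", h)
        for lvl in range(cfg.n_levels - 2, -1, -1):
            h = ag.upsample_nearest(h, 2)
            h = self._conv(f"up{lvl}.smooth", h)
            s = self._conv(f"up{lvl}.proj", skips[lvl])
            gamma, beta = self._bridge_gammabeta(lvl, Z)
            s = film_modulate(s, gamma, beta)
            h = h + s
            h = self._resblock(f"up{lvl}.block", h)
        out = self._conv("head", ag.silu(h))  # (B, 1, L)
        return ag.reshape(out, (B, cfg.segment_length))

    def __call__(self, x_t, sigma_t, x_cond) -> np.ndarray:
        """NumPy convenience wrapper (no autograd graph); keeps 1-D shape."""
        x_t = np.asarray(x_t, dtype=np.float64)
        squeeze = x_t.ndim == 1
        params = self.parameters()
        flags = [p.requires_grad for p in params]
        for p in params:
            p.requires_grad = False
        try:
            out = self.forward(x_t, sigma_t, x_cond).data
        finally:
            for p, f in zip(params, flags):
                p.requires_grad = f
        return out[0] if squeeze else out


def predict_noise(config: DenoiserConfig, model: Denoiser, x_t, sigma_t, x_cond) -> np.ndarray:
    """Functional entry point: evaluate the noise prediction as NumPy."""
    if model.config is not config and asdict(model.config) != asdict(config):
        raise ValueError("model parameters are not consistent with config")
    return model(x_t, sigma_t, x_cond)


# ----------------------------------------------------------------------
def save_checkpoint(path, model: Denoiser, extra: dict | None = None) -> None:
    """Single binary archive (.npz) with a JSON config header."""
    header = {"config": asdict(model.config), "format": "kandescod-checkpoint-v1"}
    if extra:
        header["extra"] = extra
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> Denoiser:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format") != "kandescod-checkpoint-v1":
            raise ValueError("incompatible checkpoint header")
        cfg_dict = header["config"]
        cfg_dict["grid_range"] = tuple(cfg_dict["grid_range"])
        config = DenoiserConfig(**cfg_dict)
        model = Denoiser(config)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model
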