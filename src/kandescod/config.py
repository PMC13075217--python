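"""Run configuration: YAML-backed hyperparameters with the reference
training defaults (T = 50 quadratic schedule on [1e-4, 0.5],
hidden width 80, 200 epochs, batch 96, Adam at 1e-3 with a x0.1 decay at
epoch 150, lambda_kan = 0.001)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    # spline conditioning
    grid_size: int = 5
    spline_order: int = 3
    base_activation: str = "silu"
    grid_range: tuple = (-1.0, 1.0)
    scale_base: float = 1.0
    scale_spline: float = 1.0
    standalone_scale_spline: bool = True
    # diffusion
    diffusion_steps: int = 50
    noise_schedule: str = "quadratic"
    beta_start: float = 0.0001
    beta_end: float = 0.5
    reverse_variance: str = "beta"
    conditioning_strategy: str = "signal"
    conditioning_kind: str = "kan"
    # network
    hidden_features: int = 80
    n_levels: int = 3
    blocks_per_level: int = 2
    embedding_dim: int | None = None
    segment_length: int = 512
    # training
    epochs: int = 200
    batch_size: int = 96
    learning_rate: float = 1.0e-3
    lr_gamma: float = 0.1
    lr_step: int = 150
    max_steps: int | None = None  # optional cap for CPU-scale smoke runs
    optimizer: str = "adam"
    # regularization
    lambda_kan: float = 0.001
    gamma_a: float = 1.0
    gamma_e: float = 1.0
    entropy_sign: float = 1.0
    # inference / data
    shots: tuple = (1, 3, 5, 10)
    seed: int = 0
    n_records_train: int = 10
    n_records_test: int = 4
    segments_per_record: int = 30
    data_dir: str = "data"
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_range"] = list(d["grid_range"])
        d["shots"] = list(d["shots"])
        return d


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, overrides win."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid_range" in raw:
        raw["grid_range"] = tuple(raw["grid_range"])
    if "shots" in raw:
        raw["shots"] = tuple(raw["shots"])
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
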