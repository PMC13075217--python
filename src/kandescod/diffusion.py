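"""Noise schedule, closed-form forward diffusion, conditional reverse
sampling, and multi-shot averaged inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseSchedule", "make_quadratic_schedule", "forward_diffuse",
    "reverse_step", "sample", "multi_shot_denoise",
]


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSchedule:
    """beta/alpha sequences and derived sampling coefficients (1-based t)."""

    T: int
    beta: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    alpha_bar: np.ndarray = field(repr=False)
    posterior_var: np.ndarray = field(repr=False)

    def sigma_scale(self, t: int) -> float:
        """Noise scale fed to the conditioning encoder at step t: sqrt(beta_t)."""
        return float(np.sqrt(self.beta[t - 1]))


def make_quadratic_schedule(T: int, beta_start: float, beta_end: float,
                            variance: str = "beta") -> NoiseSchedule:
    """Quadratic schedule: linear in sqrt(beta), then squared; endpoints exact.

    ``variance`` selects the reverse sampling variance: "beta" (sigma_t^2 =
    beta_t) or "tilde" (the clipped posterior variance).
    """
    if T < 1:
        raise ScheduleError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_start < beta_end < 1.0):
        raise ScheduleError(f"need 0 < beta_start < beta_end < 1, got [{beta_start}, {beta_end}]")
    if T == 1:
        beta = np.array([beta_end], dtype=np.float64)
    else:
        r = np.arange(T, dtype=np.float64) / (T - 1)
        beta = (np.sqrt(beta_start) + r * (np.sqrt(beta_end) - np.sqrt(beta_start))) ** 2
        beta[0] = beta_start   # pin endpoints exactly (squaring a rounded
        beta[-1] = beta_end    # square root can be off by one ulp)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    if variance == "beta":
        posterior_var = beta.copy()
    elif variance == "tilde":
        abar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
        posterior_var = beta * (1.0 - abar_prev) / (1.0 - alpha_bar)
    else:
        raise ScheduleError(f"unknown variance kind {variance!r}")
    return NoiseSchedule(int(T), beta, alpha, alpha_bar, posterior_var)


def _check_t(t: int, T: int) -> None:
    if not (1 <= t <= T):
        raise IndexError(f"step index t={t} outside 1..{T}")


def forward_diffuse(x0: np.ndarray, t: int, eps: np.ndarray,
                    schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form marginal: x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps."""
    _check_t(t, schedule.T)
    x0 = np.asarray(x0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if x0.shape != eps.shape:
        raise ValueError(f"shape mismatch: x0 {x0.shape} vs eps {eps.shape}")
    abar = schedule.alpha_bar[t - 1]
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


def reverse_step(x_t: np.ndarray, t: int, x_noisy_cond: np.ndarray, model,
                 schedule: NoiseSchedule, rng: np.random.Generator) -> np.ndarray:
    """One ancestral sampling step; the final step (t=1) is deterministic."""
    _check_t(t, schedule.T)
    x_t = np.asarray(x_t, dtype=np.float64)
    beta_t = schedule.beta[t - 1]
    alpha_t = schedule.alpha[t - 1]
    abar_t = schedule.alpha_bar[t - 1]
    eps_hat = np.asarray(model(x_t, schedule.sigma_scale(t), x_noisy_cond))
    mu = (x_t - beta_t / np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(alpha_t)
    if t == 1:
        return mu
    return mu + np.sqrt(schedule.posterior_var[t - 1]) * rng.standard_normal(x_t.shape)


def sample(x_noisy_cond: np.ndarray, model, schedule: NoiseSchedule,
           rng: np.random.Generator) -> np.ndarray:
    """Full reverse chain from pure noise, guided by the noisy observation."""
    x_noisy_cond = np.asarray(x_noisy_cond, dtype=np.float64)
    x = rng.standard_normal(x_noisy_cond.shape)
    for t in range(schedule.T, 0, -1):
        x = reverse_step(x, t, x_noisy_cond, model, schedule, rng)
    return x


def multi_shot_denoise(x_noisy_cond: np.ndarray, model, schedule: NoiseSchedule,
                       shots: int, rng: np.random.Generator) -> np.ndarray:
    """Average of ``shots`` independent reverse chains.

    Shot streams are ``rng.spawn(shots)``, so shots=1 reproduces a single
    ``sample`` run on the first spawned child of the same master stream.
    """
    if shots < 1:
        raise ValueError(f"shots must be >= 1, got {shots}")
    children = rng.spawn(shots)
    acc = np.zeros_like(np.asarray(x_noisy_cond, dtype=np.float64))
    for child in children:
        acc += sample(x_noisy_cond, model, schedule, child)
    return acc / shots
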