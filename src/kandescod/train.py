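"""Training loop: L1 noise-reconstruction loss plus the spline-weight
regularizer, optimised with Adam and a step LR decay."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autograd import Adam
from .backbone import Denoiser
from .diffusion import NoiseSchedule, forward_diffuse
from .objective import LossWeights, kan_reg_loss, main_loss, total_loss

__all__ = ["TrainResult", "train_denoiser"]


@dataclass
class TrainResult:
    model: Denoiser
    history: pd.DataFrame  # per-epoch losses
    best_state: dict       # parameters at the best validation loss
    best_val: float
    resume_state: dict = None  # optimizer/rng/model state to continue training


def _pairs_to_arrays(pairs):
    clean = np.stack([p.clean for p in pairs])
    noisy = np.stack([p.noisy for p in pairs])
    return clean, noisy


def _epoch_losses(model, schedule, clean, noisy, loss_weights, rng, batch_size,
                  optimizer=None):
    """One pass over the data; updates parameters when an optimizer is given."""
    n = clean.shape[0]
    order = rng.permutation(n)
    tot_main = tot_reg = tot_total = 0.0
    n_batches = 0
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        x0, cond = clean[idx], noisy[idx]
        t = rng.integers(1, schedule.T + 1, size=len(idx))
        eps = rng.standard_normal(x0.shape)
        abar = schedule.alpha_bar[t - 1][:, None]
        x_t = np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps
        sig = np.sqrt(schedule.beta[t - 1])
        pred = model.forward(x_t, sig, cond)
        lm = main_loss(pred, eps)
        spline = model.spline_weight_tensors()
        if spline and loss_weights.lambda_kan > 0:
            lr_ = kan_reg_loss(spline, loss_weights)
        else:
            lr_ = 0.0
        loss = total_loss(lm, lr_, loss_weights)
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        tot_main += float(lm.data)
        tot_reg += float(lr_.data) if hasattr(lr_, "data") else float(lr_)
        tot_total += float(loss.data)
        n_batches += 1
        if optimizer is not None and getattr(optimizer, "_step_budget", None) is not None:
            optimizer._step_budget -= 1
            if optimizer._step_budget <= 0:
                break
    return tot_main / n_batches, tot_reg / n_batches, tot_total / n_batches


def train_denoiser(model: Denoiser, schedule: NoiseSchedule, train_pairs,
                   val_pairs=None, *, loss_weights: LossWeights = LossWeights(),
                   epochs: int = 200, batch_size: int = 96, lr: float = 1e-3,
                   lr_gamma: float = 0.1, lr_step: int = 150,
                   max_steps: int | None = None, seed: int = 0,
                   resume: dict | None = None, log_fn=None) -> TrainResult:
    """Train in place; returns the per-epoch history and the best-validation
    parameter snapshot (selected by validation total loss when a validation
    set is given, else by training total loss).

    Passing a previous result's ``resume_state`` continues the run bitwise
    identically to an uninterrupted one (optimizer moments, LR schedule and
    the data-order RNG are all restored).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7261]))
    opt = Adam(model.parameters(), lr=lr)
    opt._step_budget = max_steps
    start_epoch = 1
    if resume is not None:
        model.load_state_dict(resume["model"])
        opt.load_state_dict(resume["adam"])
        rng.bit_generator.state = resume["rng"]
        start_epoch = resume["epochs_done"] + 1
        opt.lr = resume["lr"]
    clean_tr, noisy_tr = _pairs_to_arrays(train_pairs)
    have_val = val_pairs is not None and len(val_pairs) > 0
    if have_val:
        clean_va, noisy_va = _pairs_to_arrays(val_pairs)
    rows = []
    best_val = np.inf
    best_state = model.state_dict()
    for epoch in range(start_epoch, epochs + 1):
        if epoch == lr_step + 1:
            opt.lr *= lr_gamma
        m, r, tot = _epoch_losses(model, schedule, clean_tr, noisy_tr,
                                  loss_weights, rng, batch_size, optimizer=opt)
        row = {"epoch": epoch, "lr": opt.lr, "main": m, "reg": r, "total": tot}
        if have_val:
            vm, vr, vtot = _epoch_losses(model, schedule, clean_va, noisy_va,
                                         loss_weights, rng, batch_size, optimizer=None)
            row.update({"val_main": vm, "val_reg": vr, "val_total": vtot})
            monitor = vtot
        else:
            monitor = tot
        if monitor < best_val:
            best_val = monitor
            best_state = model.state_dict()
        rows.append(row)
        if log_fn is not None:
            log_fn(row)
        if opt._step_budget is not None and opt._step_budget <= 0:
            break
    resume_state = {"model": model.state_dict(), "adam": opt.state_dict(),
                    "rng": rng.bit_generator.state, "epochs_done": epoch,
                    "lr": opt.lr}
    return TrainResult(model, pd.DataFrame(rows), best_state, float(best_val),
                       resume_state)
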