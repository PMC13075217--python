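"""Signal-fidelity, waveform-similarity and timing metrics, plus
noise-level stratified aggregation of per-segment results."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport", "ssd", "mad", "prd", "prd_raw", "cossim",
    "mean_inference_time", "segment_metrics", "stratify_by_noise_level",
    "NOISE_BINS", "write_report_csv",
]

# amplitude-factor strata; left-closed/right-open, final bin closed
NOISE_BINS = ((0.2, 0.6), (0.6, 1.0), (1.0, 1.5), (1.5, 2.0))

METRIC_COLUMNS = ("ssd", "mad", "prd", "cossim")


@dataclass(frozen=True)
class MetricsReport:
    ssd: float      # mV^2
    mad: float      # mV
    prd: float      # percent
    cossim: float   # dimensionless
    n_samples: int
    mu_x: float     # clean-signal mean, mV


def _pair(x, xhat):
    x = np.asarray(x, dtype=np.float64).ravel()
    xhat = np.asarray(xhat, dtype=np.float64).ravel()
    if x.shape != xhat.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xhat.shape}")
    return x, xhat


def ssd(x, xhat) -> float:
    """Sum of squared distances."""
    x, xhat = _pair(x, xhat)
    return float(np.sum((x - xhat) ** 2))


def mad(x, xhat) -> float:
    """Maximum absolute distance."""
    x, xhat = _pair(x, xhat)
    return float(np.max(np.abs(x - xhat)))


def prd(x, xhat) -> float:
    """Percentage RMS difference with mean-subtracted reference energy."""
    x, xhat = _pair(x, xhat)
    denom = np.sum((x - np.mean(x)) ** 2)
    if denom <= 0.0:
        raise ValueError("PRD undefined for a constant reference signal")
    return float(100.0 * np.sqrt(np.sum((x - xhat) ** 2) / denom))


def prd_raw(x, xhat) -> float:
    """PRD variant without mean subtraction in the denominator."""
    x, xhat = _pair(x, xhat)
    denom = np.sum(x ** 2)
    if denom <= 0.0:
        raise ValueError("PRD undefined for an all-zero reference signal")
    return float(100.0 * np.sqrt(np.sum((x - xhat) ** 2) / denom))


def cossim(x, xhat) -> float:
    """Cosine similarity of the two signal vectors."""
    x, xhat = _pair(x, xhat)
    nx = np.sqrt(np.sum(x ** 2))
    nxh = np.sqrt(np.sum(xhat ** 2))
    if nx == 0.0 or nxh == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm signal")
    return float(np.sum(x * xhat) / (nx * nxh))


def mean_inference_time(times) -> float:
    times = np.asarray(times, dtype=np.float64)
    if times.size < 1:
        raise ValueError("need at least one timing sample")
    return float(np.mean(times))


def segment_metrics(x, xhat) -> MetricsReport:
    x_arr = np.asarray(x, dtype=np.float64).ravel()
    return MetricsReport(ssd(x, xhat), mad(x, xhat), prd(x, xhat), cossim(x, xhat),
                         x_arr.size, float(np.mean(x_arr)))


def _bin_index(factor: float) -> int | None:
    for i, (lo, hi) in enumerate(NOISE_BINS):
        if lo <= factor < hi:
            return i
    if factor == NOISE_BINS[-1][1]:
        return len(NOISE_BINS) - 1
    return None


def stratify_by_noise_level(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-segment metrics into the four amplitude strata.

    ``table`` needs a ``factor`` column plus metric columns (``ssd``,
    ``mad``, ``prd``, ``cossim``, and optionally ``time``).  Rows whose
    factor falls outside [0.2, 2.0] are excluded with a warning.  Returns
    one row per stratum with per-segment means and the segment count ``n``.
    """
    table = pd.DataFrame(table)
    idx = table["factor"].map(_bin_index)
    n_bad = int(idx.isna().sum())
    if n_bad:
        warnings.warn(f"excluded {n_bad} pair(s) with amplitude factor outside [0.2, 2.0]")
        table = table[idx.notna()]
        idx = idx[idx.notna()]
    cols = [c for c in (*METRIC_COLUMNS, "time") if c in table.columns]
    rows = []
    for i, (lo, hi) in enumerate(NOISE_BINS):
        sub = table[idx == i]
        row = {"noise_interval": f"{lo}-{hi}", "n": len(sub)}
        for c in cols:
            row[c] = float(sub[c].mean()) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_csv(path, per_segment: pd.DataFrame, model: str, shots: int) -> pd.DataFrame:
    """Write a stratified report (one row per model x shots x stratum)."""
    report = stratify_by_noise_level(per_segment)
    report.insert(0, "model", model)
    report.insert(1, "shots", shots)
    report.to_csv(path, index=False)
    return report
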