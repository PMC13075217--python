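"""Uniform B-spline grids and Cox–de Boor basis evaluation.

The grid counts *points*: ``G`` uniformly spaced interior knots on
``[range_lo, range_hi]``, extended by ``k`` uniformly spaced knots on each
side, yielding ``G + k - 1`` order-``k`` basis functions.  Inputs are
clamped into the grid range before evaluation so the basis always forms a
partition of unity (the conditioning embeddings that feed these splines are
sin/cos outputs bounded in [-1, 1], matching the default range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineGrid", "build_grid", "basis_order0", "basis", "basis_matrix"]


class InvalidGridError(ValueError):
    pass


@dataclass(frozen=True)
class SplineGrid:
    """Fixed uniform knot layout shared by every spline conditioning layer."""

    G: int
    k: int
    range_lo: float
    range_hi: float
    interior_knots: np.ndarray = field(repr=False)
    extended_knots: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return self.G + self.k - 1

    @property
    def spacing(self) -> float:
        return (self.range_hi - self.range_lo) / (self.G - 1)


def build_grid(G: int, k: int, range_lo: float, range_hi: float) -> SplineGrid:
    """Build a uniform grid of ``G`` points with ``k`` extension knots per side."""
    if G < 2:
        raise InvalidGridError(f"need at least 2 grid points, got G={G}")
    if k < 0:
        raise InvalidGridError(f"spline order must be non-negative, got k={k}")
    if not (np.isfinite(range_lo) and np.isfinite(range_hi)) or range_lo >= range_hi:
        raise InvalidGridError(f"degenerate range [{range_lo}, {range_hi}]")
    h = (range_hi - range_lo) / (G - 1)
    interior = range_lo + h * np.arange(G, dtype=np.float64)
    extended = range_lo + h * np.arange(-k, G + k, dtype=np.float64)
    return SplineGrid(int(G), int(k), float(range_lo), float(range_hi), interior, extended)


def _clamp(grid: SplineGrid, z: np.ndarray) -> np.ndarray:
    # right endpoint folded into the last interval: clamp just below range_hi
    hi = np.nextafter(grid.range_hi, grid.range_lo)
    return np.clip(z, grid.range_lo, hi)


def _check_finite(z) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("spline input must be finite")
    return z


def basis_order0(grid: SplineGrid, z: float) -> np.ndarray:
    """Indicator of each knot interval (left-closed, right-open)."""
    z = float(_check_finite(z))
    zc = _clamp(grid, z)
    s = grid.extended_knots
    return ((s[:-1] <= zc) & (zc < s[1:])).astype(np.float64)


def _basis_rows(grid: SplineGrid, Z: np.ndarray) -> np.ndarray:
    """Vectorised Cox–de Boor recursion; Z: (m,) -> (m, n_basis)."""
    Zc = _clamp(grid, Z)[:, None]
    s = grid.extended_knots
    B = ((s[None, :-1] <= Zc) & (Zc < s[None, 1:])).astype(np.float64)
    for r in range(1, grid.k + 1):
        n = B.shape[1] - 1
        left_den = s[r:r + n] - s[:n]
        right_den = s[r + 1:r + 1 + n] - s[1:1 + n]
        # uniform knots make denominators positive, but guard 0/0 := 0 anyway
        left = np.where(left_den != 0, (Zc - s[None, :n]) / left_den, 0.0) * B[:, :n]
        right = np.where(right_den != 0, (s[None, r + 1:r + 1 + n] - Zc) / right_den, 0.0) * B[:, 1:1 + n]
        B = left + right
    return B


def basis(grid: SplineGrid, z: float) -> np.ndarray:
    """Order-``k`` basis values at ``z``; length ``n_basis``, sums to 1 in range."""
    z = _check_finite(z)
    return _basis_rows(grid, np.atleast_1d(z))[0]


def basis_matrix(grid: SplineGrid, Z) -> np.ndarray:
    """Row ``j`` is ``basis(grid, Z[j])``; shape (m, n_basis)."""
    Z = _check_finite(Z)
    return _basis_rows(grid, np.asarray(Z, dtype=np.float64).ravel())
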