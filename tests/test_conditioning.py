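"""Noise-level encoding and the linear / spline affine conditioning layers."""

import math

import numpy as np
import pytest

from kandescod._autograd import Tensor
from kandescod.conditioning import (KANLayerParams, LinearAffineParams,
                                    film_modulate, init_kan_affine,
                                    init_linear_affine, kan_affine,
                                    linear_affine, positional_encode)
from kandescod.splines import basis, build_grid


# --- positional encoding ------------------------------------------------
def test_encode_zero_sigma():
    emb = positional_encode(0.0, 4)
    np.testing.assert_array_equal(emb.z, [0.0, 1.0, 0.0, 1.0])


def test_lambda_value():
    emb = positional_encode(1.0, 4)
    assert emb.lam == math.log(10000.0) / 2


def test_encode_matches_termwise_loop():
    # hand-rolled, term-by-term transcription of the sin/cos definition
    sigma, d = 1.0, 8
    lam = math.log(10000.0) / (d / 2)
    expected = []
    for j in range(d // 2):
        expected.append(math.sin(sigma * math.exp(-j * lam)))
        expected.append(math.cos(sigma * math.exp(-j * lam)))
    emb = positional_encode(sigma, d)
    np.testing.assert_allclose(emb.z, expected, atol=1e-14)


def test_encode_bounded():
    for s in (0.0, 0.01, 0.7, 5.0, 1e3):
        emb = positional_encode(s, 16)
        assert np.all(np.abs(emb.z) <= 1.0)


@pytest.mark.parametrize("d", [1, 3, 0])
def test_encode_rejects_odd_dim(d):
    with pytest.raises(ValueError):
        positional_encode(1.0, d)


def test_encode_rejects_negative_sigma():
    with pytest.raises(ValueError):
        positional_encode(-0.1, 4)


# --- linear affine ------------------------------------------------------
def test_linear_zero_map():
    p = LinearAffineParams(np.zeros((6, 4)), np.zeros(6))
    gamma, beta = linear_affine(p, np.ones(4))
    np.testing.assert_array_equal(gamma, 0.0)
    np.testing.assert_array_equal(beta, 0.0)


def test_linear_basis_vector_probe():
    W = np.arange(24, dtype=float).reshape(6, 4)
    p = LinearAffineParams(W, np.zeros(6))
    e1 = np.eye(4)[0]
    gamma, beta = linear_affine(p, e1)
    np.testing.assert_array_equal(gamma, W[:3, 0])
    np.testing.assert_array_equal(beta, W[3:, 0])


def test_linear_matches_matvec_oracle(rng):
    W = rng.standard_normal((10, 6))
    b = rng.standard_normal(10)
    z = rng.standard_normal(6)
    gamma, beta = linear_affine(LinearAffineParams(W, b), z)
    ref = W @ z + b
    np.testing.assert_allclose(np.concatenate([gamma, beta]), ref, atol=1e-14)


def test_linear_shape_error():
    p = LinearAffineParams(np.zeros((6, 4)), np.zeros(6))
    with pytest.raises(ValueError):
        linear_affine(p, np.ones(5))


# --- kan affine ---------------------------------------------------------
def _kan_params(rng, C=3, d=4, **kw):
    grid = build_grid(5, 3, -1, 1)
    return init_kan_affine(rng, C, d, grid, trainable=False, **kw)


def test_kan_reduces_to_linear_with_zero_spline(rng):
    p = _kan_params(rng, base_activation="identity")
    p.W_spline = np.zeros_like(p.W_spline)
    z = rng.uniform(-1, 1, 4)
    gamma, beta = kan_affine(p, z)
    ref = p.W_base @ z
    np.testing.assert_array_equal(np.concatenate([gamma, beta]), ref)


def test_kan_silu_zero_input_kills_base_path(rng):
    p = _kan_params(rng)
    z = np.zeros(4)
    gamma, beta = kan_affine(p, z)
    grid = p.grid
    nb = grid.n_basis
    Bz = np.tile(basis(grid, 0.0), 4)
    ref = p.scale_spline * (p.W_spline * np.repeat(p.spline_scale, nb, axis=1)) @ Bz
    np.testing.assert_allclose(np.concatenate([gamma, beta]), ref, atol=1e-14)


def test_kan_matches_double_sum_oracle(rng):
    """Explicit summation over inputs and basis functions, no matrix ops."""
    p = _kan_params(rng)
    p.W_spline = rng.standard_normal(p.W_spline.shape) * 0.3
    p.spline_scale = rng.uniform(0.5, 1.5, p.spline_scale.shape)
    z = rng.uniform(-1, 1, 4)
    nb = p.grid.n_basis
    act = z / (1.0 + np.exp(-z))
    expected = np.zeros(6)
    for o in range(6):
        for i in range(4):
            expected[o] += p.scale_base * p.W_base[o, i] * act[i]
            bvals = basis(p.grid, z[i])
            for j in range(nb):
                expected[o] += (p.scale_spline * p.spline_scale[o, i]
                                * p.W_spline[o, i * nb + j] * bvals[j])
    gamma, beta = kan_affine(p, z)
    np.testing.assert_allclose(np.concatenate([gamma, beta]), expected, atol=1e-12)


def test_kan_standalone_scale_disabled_is_plain_two_path(rng):
    p = _kan_params(rng, standalone_scale_spline=False)
    assert p.spline_scale is None
    p2 = _kan_params(rng, standalone_scale_spline=True)
    p2.W_base, p2.W_spline = p.W_base, p.W_spline
    z = rng.uniform(-1, 1, 4)
    g1, b1 = kan_affine(p, z)
    g2, b2 = kan_affine(p2, z)  # unit scales: identical
    np.testing.assert_allclose(np.concatenate([g1, b1]), np.concatenate([g2, b2]), atol=1e-14)


def test_kan_weight_shapes(rng):
    p = _kan_params(rng, C=5, d=6)
    assert p.W_base.shape == (10, 6)
    assert p.W_spline.shape == (10, 6 * p.grid.n_basis)
    assert p.n_channels == 5


def test_kan_shape_error(rng):
    p = _kan_params(rng)
    with pytest.raises(ValueError):
        kan_affine(p, np.zeros(7))


def test_kan_tensor_path_matches_numpy(rng):
    pn = _kan_params(rng)
    pn.W_spline = rng.standard_normal(pn.W_spline.shape) * 0.2
    pt = KANLayerParams(pn.grid, Tensor(pn.W_base, requires_grad=True),
                        Tensor(pn.W_spline, requires_grad=True),
                        Tensor(pn.spline_scale, requires_grad=True))
    z = rng.uniform(-1, 1, 4)
    gn, bn = kan_affine(pn, z)
    gt, bt = kan_affine(pt, z)
    np.testing.assert_allclose(gt.data, gn, atol=1e-14)
    np.testing.assert_allclose(bt.data, bn, atol=1e-14)


# --- film modulation ----------------------------------------------------
def test_film_identity():
    h = np.arange(12.0).reshape(3, 4)
    out = film_modulate(h, np.zeros(3), np.zeros(3))
    np.testing.assert_array_equal(out, h)


def test_film_direct_example():
    h = np.array([[1.0], [2.0]])
    out = film_modulate(h, np.array([1.0, 1.0]), np.array([0.5, -0.5]))
    np.testing.assert_array_equal(out.ravel(), [2.5, 3.5])


def test_film_matches_loop_oracle(rng):
    h = rng.standard_normal((2, 3, 5))
    gamma = rng.standard_normal((2, 3))
    beta = rng.standard_normal((2, 3))
    out = film_modulate(h, gamma, beta)
    for b in range(2):
        for c in range(3):
            for l in range(5):
                expected = (1 + gamma[b, c]) * h[b, c, l] + beta[b, c]
                assert abs(out[b, c, l] - expected) < 1e-14


def test_film_channel_mismatch():
    with pytest.raises(ValueError):
        film_modulate(np.zeros((3, 4)), np.zeros(2), np.zeros(2))


def test_film_tensor_path(rng):
    h = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
    gamma = rng.standard_normal((2, 3))
    beta = rng.standard_normal((2, 3))
    out = film_modulate(h, gamma, beta)
    np.testing.assert_allclose(out.data, film_modulate(h.data, gamma, beta), atol=1e-14)


# --- linear-reduction invariant (ablation hinge) ------------------------
def test_linear_reduction_equivalence(rng):
    grid = build_grid(5, 3, -1, 1)
    kan = init_kan_affine(rng, 4, 6, grid, base_activation="identity", trainable=False)
    kan.W_spline = np.zeros_like(kan.W_spline)
    lin = LinearAffineParams(kan.W_base.copy(), np.zeros(8))
    z = rng.uniform(-1, 1, 6)
    gk, bk = kan_affine(kan, z)
    gl, bl = linear_affine(lin, z)
    np.testing.assert_array_equal(gk, gl)
    np.testing.assert_array_equal(bk, bl)
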