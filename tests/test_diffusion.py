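"""Schedule construction, forward marginals, reverse sampling, multi-shot."""

import math

import numpy as np
import pytest

from kandescod.diffusion import (NoiseSchedule, ScheduleError, forward_diffuse,
                                 make_quadratic_schedule, multi_shot_denoise,
                                 reverse_step, sample)


class StubModel:
    """Returns a fixed vector regardless of input."""

    def __init__(self, value):
        self.value = np.asarray(value, dtype=np.float64)

    def __call__(self, x_t, sigma_t, x_cond):
        return np.broadcast_to(self.value, np.shape(x_t)).copy()


def zero_variance_schedule(T=4):
    beta = np.linspace(0.01, 0.2, T)
    alpha = 1 - beta
    return NoiseSchedule(T, beta, alpha, np.cumprod(alpha), np.zeros(T))


# --- schedule -----------------------------------------------------------
def test_default_endpoints_exact():
    s = make_quadratic_schedule(50, 0.0001, 0.5)
    assert s.beta[0] == 0.0001
    assert s.beta[-1] == 0.5


def test_two_step_schedule_is_endpoints():
    s = make_quadratic_schedule(2, 0.0001, 0.5)
    np.testing.assert_array_equal(s.beta, [0.0001, 0.5])


def test_schedule_matches_literal_formula_oracle():
    T, b0, b1 = 50, 0.0001, 0.5
    s = make_quadratic_schedule(T, b0, b1)
    import decimal
    decimal.getcontext().prec = 50
    d0 = decimal.Decimal(b0).sqrt()
    d1 = decimal.Decimal(b1).sqrt()
    abar = decimal.Decimal(1)
    for t in range(1, T + 1):
        beta = (d0 + decimal.Decimal(t - 1) / (T - 1) * (d1 - d0)) ** 2
        if 1 < t < T:  # endpoints are pinned exactly by construction
            assert abs(float(beta) - s.beta[t - 1]) / float(beta) < 1e-12
        abar *= 1 - decimal.Decimal(s.beta[t - 1].item())
        assert abs(float(abar) - s.alpha_bar[t - 1]) / float(abar) < 1e-12


def test_schedule_monotonicity():
    s = make_quadratic_schedule(50, 0.0001, 0.5)
    assert np.all(np.diff(s.beta) > 0)
    assert np.all(np.diff(s.alpha_bar) < 0)
    assert np.all(s.alpha_bar > 0) and np.all(s.alpha_bar <= 1)
    assert np.all(s.posterior_var >= 0)


def test_tilde_variance_first_step_zero():
    s = make_quadratic_schedule(10, 0.0001, 0.5, variance="tilde")
    assert s.posterior_var[0] == 0.0
    assert np.all(s.posterior_var >= 0)


@pytest.mark.parametrize("args", [(0, 0.1, 0.2), (10, 0.2, 0.1), (10, 0.0, 0.5),
                                  (10, 0.1, 1.0)])
def test_schedule_invalid_bounds(args):
    with pytest.raises(ScheduleError):
        make_quadratic_schedule(*args)


# --- forward ------------------------------------------------------------
def test_forward_zero_noise_limit():
    s = make_quadratic_schedule(5, 1e-12, 2e-12)
    x0 = np.ones(8)
    x_t = forward_diffuse(x0, 5, np.zeros(8), s)
    np.testing.assert_allclose(x_t, x0, atol=1e-10)


def test_forward_linearity_in_eps(rng):
    s = make_quadratic_schedule(10, 0.0001, 0.5)
    eps = rng.standard_normal(16)
    x_t = forward_diffuse(np.zeros(16), 7, eps, s)
    np.testing.assert_allclose(x_t, np.sqrt(1 - s.alpha_bar[6]) * eps, atol=1e-14)


def test_forward_out_of_range_t():
    s = make_quadratic_schedule(10, 0.0001, 0.5)
    with pytest.raises(IndexError):
        forward_diffuse(np.zeros(4), 0, np.zeros(4), s)
    with pytest.raises(IndexError):
        forward_diffuse(np.zeros(4), 11, np.zeros(4), s)


def test_forward_marginal_moments_monte_carlo():
    s = make_quadratic_schedule(50, 0.0001, 0.5)
    t = 25
    rng = np.random.default_rng(99)
    x0 = np.array([0.7, -0.4, 1.2, 0.0])
    draws = np.stack([forward_diffuse(x0, t, rng.standard_normal(4), s)
                      for _ in range(20000)])
    abar = s.alpha_bar[t - 1]
    se_mean = math.sqrt((1 - abar) / 20000)
    assert np.all(np.abs(draws.mean(0) - np.sqrt(abar) * x0) < 4 * se_mean)
    se_var = (1 - abar) * math.sqrt(2 / (20000 - 1))
    assert np.all(np.abs(draws.var(0, ddof=1) - (1 - abar)) < 4 * se_var)


# --- reverse ------------------------------------------------------------
def test_reverse_final_step_zero_prediction():
    s = make_quadratic_schedule(3, 0.0001, 0.5)
    model = StubModel(np.zeros(6))
    x1 = np.full(6, 2.0)
    out = reverse_step(x1, 1, np.zeros(6), model, s, np.random.default_rng(0))
    np.testing.assert_allclose(out, x1 / np.sqrt(s.alpha[0]), atol=1e-14)
    # deterministic: rng state must not matter at t = 1
    out2 = reverse_step(x1, 1, np.zeros(6), model, s, np.random.default_rng(42))
    np.testing.assert_array_equal(out, out2)


def test_zero_variance_chain_is_deterministic():
    s = zero_variance_schedule()
    model = StubModel(np.full(6, 0.3))
    cond = np.zeros(6)
    a = sample(cond, model, s, np.random.default_rng(1))
    b = sample(cond, model, s, np.random.default_rng(1))
    np.testing.assert_array_equal(a, b)


def test_two_step_hand_unrolled_oracle():
    s = make_quadratic_schedule(2, 0.0001, 0.5, variance="beta")
    v = np.array([0.1, -0.2, 0.3])
    model = StubModel(v)
    rng = np.random.default_rng(7)
    x2 = np.array([1.0, 0.5, -1.0])
    # replicate the chain by hand with a cloned rng
    rng_ref = np.random.default_rng(7)
    mu2 = (x2 - s.beta[1] / np.sqrt(1 - s.alpha_bar[1]) * v) / np.sqrt(s.alpha[1])
    x1_ref = mu2 + np.sqrt(s.posterior_var[1]) * rng_ref.standard_normal(3)
    x0_ref = (x1_ref - s.beta[0] / np.sqrt(1 - s.alpha_bar[0]) * v) / np.sqrt(s.alpha[0])
    x1 = reverse_step(x2, 2, np.zeros(3), model, s, rng)
    x0 = reverse_step(x1, 1, np.zeros(3), model, s, rng)
    assert np.max(np.abs(x0 - x0_ref)) < 1e-12


def test_sample_seeded_determinism():
    s = make_quadratic_schedule(5, 0.0001, 0.5)
    model = StubModel(np.zeros(8))
    cond = np.zeros(8)
    a = sample(cond, model, s, np.random.default_rng(3))
    b = sample(cond, model, s, np.random.default_rng(3))
    np.testing.assert_array_equal(a, b)
    assert a.shape == (8,)


def test_sample_zero_prediction_chain_mean():
    # under eps_hat = 0 the chain is linear-Gaussian with mean 0
    s = make_quadratic_schedule(5, 0.0001, 0.5)
    model = StubModel(np.zeros(4))
    outs = np.stack([sample(np.zeros(4), model, s, np.random.default_rng(seed))
                     for seed in range(1000)])
    # analytic per-seed variance of the chain output
    scale = 1.0
    var = 0.0
    for t in range(s.T, 0, -1):
        c = 1.0 / np.sqrt(s.alpha[t - 1])
        var = c ** 2 * var + (s.posterior_var[t - 1] if t > 1 else 0.0)
        if t == s.T:
            var = c ** 2 * 1.0  # x_T ~ N(0, 1)
        scale *= c
    se = math.sqrt(var / outs.size)
    assert abs(outs.mean()) < 4 * se


# --- multi-shot ---------------------------------------------------------
def test_single_shot_equals_sample_on_spawned_stream():
    s = make_quadratic_schedule(5, 0.0001, 0.5)
    model = StubModel(np.zeros(8))
    cond = np.zeros(8)
    ms = multi_shot_denoise(cond, model, s, 1, np.random.default_rng(11))
    single = sample(cond, model, s, np.random.default_rng(11).spawn(1)[0])
    np.testing.assert_array_equal(ms, single)


def test_multi_shot_zero_variance_hand_average():
    # with zero step variance each shot is a deterministic affine function of
    # its own starting draw; the multi-shot output is their hand-computed mean
    s = zero_variance_schedule()
    model = StubModel(np.full(6, 0.2))
    cond = np.zeros(6)
    three = multi_shot_denoise(cond, model, s, 3, np.random.default_rng(5))
    ref = np.zeros(6)
    for child in np.random.default_rng(5).spawn(3):
        x = child.standard_normal(6)
        for t in range(s.T, 0, -1):
            mu = (x - s.beta[t - 1] / np.sqrt(1 - s.alpha_bar[t - 1]) * model.value) \
                / np.sqrt(s.alpha[t - 1])
            x = mu
        ref += x / 3
    np.testing.assert_allclose(three, ref, atol=1e-12)


def test_multi_shot_rejects_zero_shots():
    s = make_quadratic_schedule(3, 0.0001, 0.5)
    with pytest.raises(ValueError):
        multi_shot_denoise(np.zeros(4), StubModel(np.zeros(4)), s, 0,
                           np.random.default_rng(0))


def test_multi_shot_variance_halves_with_two_shots():
    # light version of the 1/shots averaging law (full check in acceptance)
    s = make_quadratic_schedule(5, 0.0001, 0.5)
    model = StubModel(np.zeros(16))
    cond = np.zeros(16)
    one = np.stack([multi_shot_denoise(cond, model, s, 1, np.random.default_rng(i))
                    for i in range(150)])
    two = np.stack([multi_shot_denoise(cond, model, s, 2, np.random.default_rng(i))
                    for i in range(150)])
    ratio = two.var(axis=0, ddof=1).mean() / one.var(axis=0, ddof=1).mean()
    assert 0.35 < ratio < 0.7
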