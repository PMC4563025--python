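"""Forward-model behavior: update rules, scaling, and nesting identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pescale.models import (
    ModelParams,
    running_sd_sequence,
    scaling_factor,
    simulate_adaptive_ph,
    simulate_ph,
    simulate_rw,
    update_running_sd,
)


def test_rw_single_step():
    tr = simulate_rw([60], alpha=0.5, p1=50)
    assert tr.deltas[0] == 10
    assert tr.final_prediction == 55


def test_rw_degenerate_rates():
    r = [40, 70, 55, 30]
    frozen = simulate_rw(r, alpha=0.0, p1=50)
    assert np.all(frozen.predictions == 50)
    full = simulate_rw(r, alpha=1.0, p1=50)
    assert np.array_equal(full.predictions[1:], np.asarray(r[:-1], float))


def test_rw_rejects_bad_alpha():
    with pytest.raises(ValueError):
        simulate_rw([50], alpha=1.5, p1=50)


def test_ph_learning_rate_update():
    # alpha=0.5, eta=0.1, |delta|=20 -> next alpha = 0.1*0.2 + 0.9*0.5 = 0.47
    tr = simulate_ph([70], alpha1=0.5, eta=0.1, p1=50)
    assert tr.final_alpha == pytest.approx(0.47)


def test_ph_alpha_decays_geometrically_with_zero_error():
    tr = simulate_ph([50] * 10, alpha1=0.8, eta=0.3, p1=50)
    expected = 0.8 * 0.7 ** np.arange(10)
    assert tr.alphas == pytest.approx(expected)


def test_scaling_factor_values():
    assert scaling_factor(0.0, 15.0, "log") == 1.0
    assert scaling_factor(1.0, 15.0, "linear") == 15.0  # delta 15 -> 1 point
    assert scaling_factor(0.5, 15.0, "log") == pytest.approx(0.5 + 0.5 * math.log(15))
    assert scaling_factor(0.7, 3.0, "none") == 1.0
    with pytest.raises(ValueError):
        scaling_factor(0.5, 0.0, "log")
    with pytest.raises(ValueError):
        scaling_factor(0.5, 5.0, "cubic")


def test_scaling_factor_floor():
    # nu > 1 with small sigma would give a non-positive divisor
    assert scaling_factor(2.0, 1.0, "log") == pytest.approx(1e-3)


def test_update_running_sd():
    assert update_running_sd([30], 8.0, 1) == 8.0
    assert update_running_sd([30, 40], 8.0, 2) == 8.0  # not 7.07
    assert update_running_sd([30, 40, 50], 8.0, 3) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        update_running_sd([30], 8.0, 0)


def test_running_sd_sequence_matches_pointwise():
    r = np.random.default_rng(5).normal(50, 10, 30)
    seq = running_sd_sequence(r)
    assert np.isnan(seq[:2]).all()
    for t in range(3, 31):
        assert seq[t - 1] == pytest.approx(np.std(r[:t], ddof=1))


def _random_rewards(seed, n=42):
    return np.round(np.random.default_rng(seed).normal(50, 12, n))


@pytest.mark.parametrize("scaling", ["linear", "log"])
def test_nesting_identities_exact(scaling):
    """nu=0 reduces to PH; nu=0, eta=0 reduces to RW, bitwise."""
    for seed in range(20):
        r = _random_rewards(seed)
        ph_like = ModelParams(alpha1=0.6, eta=0.25, nu=0.0, sigma_init=9.0, scaling=scaling)
        assert np.array_equal(
            simulate_adaptive_ph(r, ph_like, 48.0).predictions,
            simulate_ph(r, 0.6, 0.25, 48.0).predictions,
        )
        rw_like = ModelParams(alpha1=0.6, eta=0.0, nu=0.0, sigma_init=9.0, scaling=scaling)
        assert np.array_equal(
            simulate_adaptive_ph(r, rw_like, 48.0).predictions,
            simulate_rw(r, 0.6, 48.0).predictions,
        )


def test_ph_eta0_equals_rw():
    r = _random_rewards(77)
    assert np.array_equal(
        simulate_ph(r, 0.35, 0.0, 51.0).predictions, simulate_rw(r, 0.35, 51.0).predictions
    )


def test_fixed_nu_variant_equals_free_at_one():
    r = _random_rewards(3)
    fixed = ModelParams(alpha1=0.5, eta=0.2, nu=1.0, sigma_init=10.0, scaling="log",
                        nu_fixed=True)
    free = ModelParams(alpha1=0.5, eta=0.2, nu=1.0, sigma_init=10.0, scaling="log")
    assert np.array_equal(
        simulate_adaptive_ph(r, fixed, 50.0).predictions,
        simulate_adaptive_ph(r, free, 50.0).predictions,
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    alpha1=st.floats(0, 1),
    eta=st.floats(0, 1),
    nu=st.floats(0, 1),
    seed=st.integers(0, 2**16),
)
def test_learning_rate_stays_in_unit_interval(alpha1, eta, nu, seed):
    r = _random_rewards(seed, n=60)
    params = ModelParams(alpha1=alpha1, eta=eta, nu=nu, sigma_init=10.0, scaling="log")
    tr = simulate_adaptive_ph(r, params, 50.0)
    assert np.all(tr.alphas >= 0) and np.all(tr.alphas <= 1)


def test_scaled_error_monotone_in_sigma():
    sigmas = np.linspace(1, 30, 50)
    for scaling in ("linear", "log"):
        for nu in (0.3, 0.8, 1.0):
            mags = 15.0 / np.array([scaling_factor(nu, s, scaling) for s in sigmas])
            assert np.all(np.diff(mags) <= 1e-12)


def test_rw_stationary_prediction_variance():
    """Long-run var(P) for i.i.d. rewards approaches sigma^2 * a / (2 - a)."""
    alpha, sigma, T, reps = 0.4, 10.0, 3000, 40
    rng = np.random.default_rng(2024)
    per_rep = []
    for _ in range(reps):
        r = rng.normal(0.0, sigma, T)
        tr = simulate_rw(r, alpha, p1=0.0)
        per_rep.append(np.var(tr.predictions[500:]))
    est = np.mean(per_rep)
    se = np.std(per_rep, ddof=1) / np.sqrt(reps)
    expected = sigma**2 * alpha / (2 - alpha)
    assert abs(est - expected) <= 3 * se


def test_adaptive_params_validation():
    with pytest.raises(ValueError):
        ModelParams(alpha1=0.5, eta=0.2, nu=1.5, sigma_init=5.0, scaling="log")
    ModelParams(alpha1=0.5, eta=0.2, nu=1.5, sigma_init=5.0, scaling="log",
                nu_unconstrained=True)  # allowed when unconstrained
    with pytest.raises(ValueError):
        ModelParams(alpha1=0.5, eta=0.2, nu=0.5, sigma_init=None, scaling="log")
    with pytest.raises(ValueError):
        ModelParams(alpha1=0.5, scaling="weird")
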