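"""Least-squares fitting, information criteria, and nested comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from pescale.cohort import CohortSpec, generate_cohort
from pescale.fitting import (
    ComparisonResult,
    ConditionData,
    FitConfig,
    FitResult,
    compare_models,
    fit_cohort,
    fit_model,
    information_criteria,
    is_nested,
    likelihood_ratio_test,
    participant_conditions,
    sse_objective,
)
from pescale.models import ModelParams, simulate_ph


def _condition(rewards, predictions, sd_level="medium", sd=10.0, ev=50.0, cid="c1"):
    return ConditionData(cid, sd_level, sd, ev, tuple(rewards), tuple(predictions))


def test_sse_objective_arithmetic():
    # RW alpha=0.5 from P1=50 with reward 60 models [50, 55]; observed [50, 60]
    cond = _condition([60, 60], [50, 60])
    cfg = FitConfig(model="rw", trial_mask=(2, 42))
    params = ModelParams(alpha1=0.5)
    assert sse_objective(params, [cond], cfg) == pytest.approx(25.0)


def test_sse_noise_free_self_consistency():
    r = np.round(np.random.default_rng(1).normal(50, 10, 42))
    tr = simulate_ph(r, 0.55, 0.2, 48.0)
    cond = _condition(r, tr.predictions)
    cfg = FitConfig(model="ph")
    assert sse_objective(ModelParams(alpha1=0.55, eta=0.2), [cond], cfg) == pytest.approx(0.0)


def test_empty_mask_is_an_error():
    cond = _condition([60, 60], [50, 60])
    cfg = FitConfig(model="rw", trial_mask=(3, 42))
    with pytest.raises(ValueError):
        sse_objective(ModelParams(alpha1=0.5), [cond], cfg)


def test_mismatched_lengths_rejected():
    with pytest.raises(ValueError):
        _condition([60, 60], [50])


def test_information_criteria_examples():
    loglik, aic, bic = information_criteria(sse=50.0, n_obs=50, k=2)
    assert aic == pytest.approx(4.0)  # n ln 1 + 2k
    _, _, bic = information_criteria(sse=100.0, n_obs=100, k=3)
    assert bic == pytest.approx(3 * math.log(100))
    ll, aic0, _ = information_criteria(sse=0.0, n_obs=10, k=1)  # epsilon floor
    assert np.isfinite(aic0) and aic0 < -100


def test_information_criteria_rejects_empty():
    with pytest.raises(ValueError):
        information_criteria(1.0, 0, 1)


def _noise_free_participant(alpha1=0.62, eta=0.27, seed=0):
    rng = np.random.default_rng(seed)
    conds = []
    for i, (lv, sd, ev) in enumerate(
        [("small", 5, 35), ("medium", 10, 65), ("large", 15, 35)]
    ):
        r = np.round(rng.normal(ev, sd, 42))
        tr = simulate_ph(r, alpha1, eta, ev + 12.0)
        conds.append(_condition(r, tr.predictions, lv, sd, ev, f"c{i}"))
    return conds


def test_noise_free_ph_recovery():
    """Fitting noise-free PH data recovers the generating parameters."""
    conds = _noise_free_participant()
    fr = fit_model(conds, FitConfig(model="ph", n_starts=6, seed=1))
    assert fr.theta["alpha1"] == pytest.approx(0.62, abs=1e-3)
    assert fr.theta["eta"] == pytest.approx(0.27, abs=1e-3)
    assert fr.sse < 1e-6
    assert fr.converged


def test_fit_beats_or_matches_truth_on_noisy_data():
    rng = np.random.default_rng(4)
    conds = []
    for c in _noise_free_participant(seed=4):
        noisy = np.asarray(c.predictions) + rng.normal(0, 3, len(c.predictions))
        conds.append(_condition(c.rewards, noisy, c.sd_level, c.sd_target, c.ev, c.condition_id))
    cfg = FitConfig(model="ph", n_starts=6, seed=2)
    fr = fit_model(conds, cfg)
    sse_truth = sse_objective(ModelParams(alpha1=0.62, eta=0.27), conds, cfg)
    assert fr.sse <= sse_truth + 1e-9


def test_nested_sse_monotonicity():
    """Richer models never fit worse than their restrictions."""
    rng = np.random.default_rng(9)
    conds = []
    for c in _noise_free_participant(seed=9):
        noisy = np.asarray(c.predictions) + rng.normal(0, 4, len(c.predictions))
        conds.append(_condition(c.rewards, noisy, c.sd_level, c.sd_target, c.ev, c.condition_id))
    sses = {
        m: fit_model(conds, FitConfig(model=m, n_starts=5, seed=3)).sse
        for m in ("rw", "ph", "ph-sd", "aph-log")
    }
    assert sses["ph"] <= sses["rw"] + 1e-6
    assert sses["ph-sd"] <= sses["ph"] + 1e-6
    assert sses["aph-log"] <= sses["ph"] + 1e-6


def test_zero_nu_bound_reproduces_ph():
    conds = _noise_free_participant(seed=5)
    ph = fit_model(conds, FitConfig(model="ph", n_starts=5, seed=5))
    pinned = fit_model(conds, FitConfig(model="aph-log", n_starts=5, seed=5, nu_bound=0.0))
    assert pinned.theta["nu"] == 0.0
    assert pinned.sse == pytest.approx(ph.sse, abs=1e-6)


def test_empirical_sigma_variant_shrinks_k():
    conds = _noise_free_participant(seed=6)
    full = fit_model(conds, FitConfig(model="aph-log", n_starts=4, seed=6))
    emp = fit_model(conds, FitConfig(model="aph-log", n_starts=4, seed=6, empirical_sigma=True))
    assert full.k - emp.k == 3  # the three initial expected SDs drop out
    assert emp.n_obs < full.n_obs  # mask starts at trial 3


def _dummy_fit(model, sse, n, k):
    return FitResult(model, ModelParams(alpha1=0.5), {}, sse, n, k,
                     *information_criteria(sse, n, k), True, ())


def test_lrt_identical_fits_is_null():
    r = _dummy_fit("rw", 100.0, 246, 1)
    f = _dummy_fit("ph", 100.0, 246, 2)
    res = likelihood_ratio_test(r, f)
    assert res.lr == 0.0 and res.p_value == 1.0 and res.df == 1


def test_lrt_df_aggregates_over_participants():
    rs = [_dummy_fit("ph", 120.0, 246, 2) for _ in range(31)]
    fs = [_dummy_fit("aph-log", 100.0, 246, 6) for _ in range(31)]
    res = likelihood_ratio_test(rs, fs)
    assert res.df_per_participant == 4  # nu + three initial expected SDs
    assert res.df == 124
    assert res.lr == pytest.approx(31 * 246 * math.log(1.2))
    assert 0 <= res.p_value <= 1


def test_lrt_rejects_non_nested_direction():
    with pytest.raises(ValueError):
        likelihood_ratio_test(_dummy_fit("ph", 90.0, 246, 2), _dummy_fit("rw", 100.0, 246, 1))


def test_lrt_clamps_optimizer_failures():
    r = _dummy_fit("rw", 100.0, 246, 1)
    f = _dummy_fit("ph", 101.0, 246, 2)  # full worse: optimizer failure
    with pytest.warns(UserWarning):
        res = likelihood_ratio_test(r, f)
    assert res.lr == 0.0


def test_nesting_relation():
    assert is_nested("rw", "ph")
    assert is_nested("ph", "aph-log")
    assert not is_nested("aph-log", "ph")
    assert not is_nested("aph-lin", "aph-log")


def test_fit_cohort_and_determinism(small_cohort):
    _, dataset, _ = small_cohort
    cfg = FitConfig(model="ph", n_starts=3, seed=7)
    fits1 = fit_cohort(dataset, cfg)
    fits2 = fit_cohort(dataset, cfg)
    assert set(fits1) == {1, 2, 3}
    for pid in fits1:
        assert fits1[pid].theta == fits2[pid].theta
        assert fits1[pid].n_obs == 6 * 41


def test_pooled_fit_returns_single_result(small_cohort):
    _, dataset, _ = small_cohort
    pooled = fit_cohort(dataset, FitConfig(model="rw", n_starts=3, seed=1, pooled=True))
    assert isinstance(pooled, FitResult)
    assert pooled.n_obs == 3 * 6 * 41


def test_compare_models_prefers_generator():
    """A cohort generated from RW is preferred by BIC for most members."""
    spec = CohortSpec(n_participants=3, model="rw", noise_sd=3.0, seed=21)
    dataset, _ = generate_cohort(spec)
    res = compare_models(dataset, ["rw", "ph"], FitConfig(n_starts=4, seed=1), criterion="bic")
    assert res["best_counts"]["rw"] >= 2
    lrt = res["lr_tests"][0]
    assert isinstance(lrt, ComparisonResult)
    assert lrt.restricted == "rw" and lrt.full == "ph"


def test_participant_conditions_roundtrip(small_cohort):
    _, dataset, _ = small_cohort
    conds = participant_conditions(dataset[dataset.participant_id == 1])
    assert len(conds) == 6
    assert all(len(c.rewards) == 42 for c in conds)
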