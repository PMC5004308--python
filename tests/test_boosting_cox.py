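"""Componentwise Cox boosting: oracle equivalence, limits and contracts."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from omicslink import (
    BoostConfig,
    SurvivalOutcome,
    breslow_cumulative_hazard,
    cox_partial_loglik,
    fit_cox_boost,
    predict_linear_predictor,
    predict_survival,
)

from conftest import random_matrix, random_outcome
from oracles import naive_cox_boost, naive_partial_loglik


def _instance(seed, n=60, d=2, q=8, ties=True):
    rng = np.random.default_rng(seed)
    outcome = random_outcome(rng, n, ties=ties)
    mand = random_matrix(rng, outcome.sample_ids, d, "c")
    opt = random_matrix(rng, outcome.sample_ids, q, "x")
    return rng, outcome, mand, opt


def test_partial_loglik_matches_bruteforce():
    rng, outcome, _, _ = _instance(0, n=40)
    eta = rng.standard_normal(outcome.n)
    expected = naive_partial_loglik(eta, outcome.time, outcome.event)
    assert cox_partial_loglik(eta, outcome.time, outcome.event) == pytest.approx(
        expected, abs=1e-10
    )


def test_path_matches_bruteforce_oracle():
    rng, outcome, mand, opt = _instance(1, n=50, d=2, q=6)
    offset = 0.3 * rng.standard_normal(outcome.n)
    penalty = 12.0
    steps = 5
    fit = fit_cox_boost(
        mand, opt, outcome, offset=offset,
        config=BoostConfig(n_steps_max=steps, penalty=penalty),
        select_step="last",
    )
    path, mand_path, _ = naive_cox_boost(
        mand.to_numpy(), opt.to_numpy(), outcome.time, outcome.event,
        offset, penalty, steps,
    )
    np.testing.assert_allclose(fit.coef_path, path, atol=1e-9)
    np.testing.assert_allclose(fit.mandatory_path, mand_path, atol=1e-8)


def test_zero_steps_match_lifelines():
    # with no boosting steps the fit is the unpenalized clinical Cox model
    rng, outcome, mand, _ = _instance(2, n=80, d=3, ties=False)
    fit = fit_cox_boost(
        mand, None, outcome, config=BoostConfig(n_steps_max=0), select_step=0
    )
    df = mand.copy()
    df["time"] = outcome.time
    df["event"] = outcome.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    np.testing.assert_allclose(
        fit.mandatory_coefficients().to_numpy(),
        cph.params_.loc[fit.mandatory_ids].to_numpy(),
        atol=1e-5,
    )


def test_constant_offset_invariance():
    # the partial likelihood is shift invariant, so a constant offset must
    # leave the whole path untouched
    _, outcome, mand, opt = _instance(3)
    cfg = BoostConfig(n_steps_max=6, penalty=20.0)
    fit0 = fit_cox_boost(mand, opt, outcome, config=cfg, select_step="last")
    fit_c = fit_cox_boost(
        mand, opt, outcome, offset=np.full(outcome.n, 3.7), config=cfg,
        select_step="last",
    )
    np.testing.assert_allclose(fit0.coef_path, fit_c.coef_path, atol=1e-10)
    np.testing.assert_allclose(fit0.mandatory_path, fit_c.mandatory_path, atol=1e-9)


def test_train_loglik_monotone_nondecreasing():
    _, outcome, mand, opt = _instance(4)
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=10, penalty=15.0),
        select_step="last",
    )
    diffs = np.diff(fit.train_criterion_path)
    assert (diffs >= -1e-9).all()


def test_path_sparsity_one_update_per_step():
    _, outcome, mand, opt = _instance(5, q=10)
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=8, penalty=15.0),
        select_step="last",
    )
    assert (fit.coef_path[0] == 0).all()
    for m in range(1, fit.n_steps + 1):
        changed = (fit.coef_path[m] != fit.coef_path[m - 1]).sum()
        assert changed <= 1
        assert (fit.coef_path[m] != 0).sum() <= m


def test_constant_feature_never_selected():
    _, outcome, mand, opt = _instance(6)
    opt = opt.copy()
    opt["x0"] = 1.0  # constant column
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=10, penalty=10.0),
        select_step="last",
    )
    assert (fit.coef_path[:, list(opt.columns).index("x0")] == 0).all()


def test_huge_penalty_freezes_optional_coefficients():
    _, outcome, mand, opt = _instance(7)
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=5, penalty=1e12),
        select_step="last",
    )
    assert np.abs(fit.coef_path).max() < 1e-8


def test_null_model_survival_equals_nelson_aalen():
    # with eta = 0 the Breslow estimate is the Nelson-Aalen cumulative hazard
    rng = np.random.default_rng(8)
    outcome = random_outcome(rng, 30, ties=False)
    H = breslow_cumulative_hazard(outcome, np.zeros(outcome.n))
    order = np.argsort(outcome.time)
    t_sorted, e_sorted = outcome.time[order], outcome.event[order]
    for t in np.quantile(outcome.time, [0.2, 0.5, 0.8]):
        expected = sum(
            e_sorted[i] / (t_sorted >= t_sorted[i]).sum()
            for i in range(len(t_sorted))
            if t_sorted[i] <= t
        )
        assert H(t) == pytest.approx(expected, abs=1e-12)


def test_predict_survival_bounded_and_monotone():
    _, outcome, mand, opt = _instance(9)
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=5, penalty=15.0),
        select_step="last",
    )
    times = np.quantile(outcome.time, [0.1, 0.3, 0.5, 0.7, 0.9])
    S = predict_survival(fit, mandatory=mand, optional=opt, times=times)
    vals = S.to_numpy()
    assert (vals >= 0).all() and (vals <= 1).all()
    assert (np.diff(vals, axis=1) <= 1e-12).all()


def test_predict_on_training_data_matches_eta_path():
    _, outcome, mand, opt = _instance(10)
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=6, penalty=15.0),
        select_step="last",
    )
    eta = predict_linear_predictor(fit, mandatory=mand, optional=opt, at_step=4)
    np.testing.assert_allclose(eta.to_numpy(), fit.eta_path[4], atol=1e-10)


def test_no_events_raises():
    ids = np.array(["a", "b", "c"], dtype=object)
    outcome = SurvivalOutcome(time=[1.0, 2.0, 3.0], event=[0, 0, 0], sample_ids=ids)
    mand = pd.DataFrame({"c0": [0.1, 0.2, 0.3]}, index=ids)
    with pytest.raises(ValueError, match="no events"):
        fit_cox_boost(mand, None, outcome, select_step=0)


def test_missing_feature_column_named_in_error():
    _, outcome, mand, opt = _instance(11)
    fit = fit_cox_boost(
        mand, opt, outcome, config=BoostConfig(n_steps_max=3, penalty=15.0),
        select_step="last",
    )
    with pytest.raises(ValueError, match="x0"):
        predict_linear_predictor(fit, mandatory=mand, optional=opt.drop(columns=["x0"]))


def test_wrong_offset_length_raises():
    _, outcome, mand, opt = _instance(12)
    with pytest.raises(ValueError, match="offset"):
        fit_cox_boost(
            mand, opt, outcome, offset=np.zeros(outcome.n - 1),
            config=BoostConfig(n_steps_max=2), select_step="last",
        )
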