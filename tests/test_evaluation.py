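"""Prediction error machinery: KM, IPCW Brier, .632+, inclusion frequencies."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from sksurv.metrics import brier_score as sksurv_brier_score

from omicslink import (
    SurvivalOutcome,
    bootstrap_632plus_mse,
    bootstrap_632plus_pec,
    brier_curve,
    censoring_km,
    clinical_cox_benchmark,
    inclusion_frequencies,
    integrated_pec,
    ipcw_weights,
    km_estimator,
)
from omicslink.evaluation import _e632plus

from conftest import random_matrix, random_outcome
from oracles import naive_brier


def _toy_outcome():
    ids = np.array(list("abcde"), dtype=object)
    return SurvivalOutcome(
        time=[1.0, 2.0, 3.0, 4.0, 5.0], event=[1, 0, 1, 1, 0], sample_ids=ids
    )


def test_km_hand_computed_values():
    km = km_estimator(_toy_outcome())
    assert km(0.5) == pytest.approx(1.0)
    assert km(1.0) == pytest.approx(0.8)
    assert km(2.5) == pytest.approx(0.8)
    assert km(3.0) == pytest.approx(8 / 15)
    assert km(4.0) == pytest.approx(4 / 15)
    assert km(5.0) == pytest.approx(4 / 15)


def test_censoring_km_without_censoring_is_one():
    ids = np.array(list("abc"), dtype=object)
    outcome = SurvivalOutcome(time=[1.0, 2.0, 3.0], event=[1, 1, 1], sample_ids=ids)
    G = censoring_km(outcome)
    assert G(0.5) == 1.0 and G(2.0) == 1.0 and G(3.0) == 1.0
    W = ipcw_weights(outcome, np.array([1.5]))
    np.testing.assert_allclose(W[:, 0], [1.0, 1.0, 1.0])


def test_brier_constant_half_without_censoring():
    rng = np.random.default_rng(0)
    outcome = random_outcome(rng, 25, event_fraction=1.0)
    outcome = SurvivalOutcome(
        time=outcome.time, event=np.ones(outcome.n, int), sample_ids=outcome.sample_ids
    )
    times = np.quantile(outcome.time, [0.2, 0.5, 0.8])
    S = np.full((outcome.n, times.size), 0.5)
    np.testing.assert_allclose(brier_curve(S, outcome, times), 0.25, atol=1e-12)


def test_brier_perfect_oracle_is_zero():
    rng = np.random.default_rng(1)
    outcome = random_outcome(rng, 25, event_fraction=1.0)
    outcome = SurvivalOutcome(
        time=outcome.time, event=np.ones(outcome.n, int), sample_ids=outcome.sample_ids
    )
    times = np.quantile(outcome.time, [0.3, 0.6])
    S = (outcome.time[:, None] > times[None, :]).astype(float)
    np.testing.assert_allclose(brier_curve(S, outcome, times), 0.0, atol=1e-12)


def test_brier_censored_toy_matches_bruteforce():
    ids = np.array(list("abcdef"), dtype=object)
    outcome = SurvivalOutcome(
        time=[1.0, 2.0, 2.5, 3.0, 4.0, 5.0],
        event=[1, 0, 1, 0, 1, 1],
        sample_ids=ids,
    )
    times = np.array([1.5, 2.75, 4.5])
    rng = np.random.default_rng(2)
    S = rng.uniform(0.1, 0.9, size=(6, 3))
    expected = naive_brier(S, outcome.time, outcome.event, times)
    np.testing.assert_allclose(brier_curve(S, outcome, times), expected, atol=1e-12)


def test_brier_cross_checks_against_sksurv():
    rng = np.random.default_rng(3)
    outcome = random_outcome(rng, 60, event_fraction=0.7, ties=False)
    times = np.quantile(outcome.time[outcome.event == 1], [0.25, 0.5, 0.75])
    S = rng.uniform(0.05, 0.95, size=(outcome.n, times.size))
    y = np.array(
        list(zip(outcome.event.astype(bool), outcome.time)),
        dtype=[("event", bool), ("time", float)],
    )
    _, expected = sksurv_brier_score(y, y, S, times)
    np.testing.assert_allclose(brier_curve(S, outcome, times), expected, atol=1e-10)


def test_632plus_degenerate_equals_apparent():
    apparent = np.array([0.1, 0.2, 0.05])
    noinf = np.array([0.3, 0.25, 0.4])
    est = _e632plus(apparent, apparent.copy(), noinf)
    np.testing.assert_array_equal(est, apparent)


def test_632plus_estimate_between_apparent_and_oob():
    apparent = np.array([0.10])
    oob = np.array([0.20])
    noinf = np.array([0.25])
    est = _e632plus(apparent, oob, noinf)
    assert apparent[0] < est[0] <= oob[0]
    # weight moves toward 1 (pure oob) as overfitting grows
    est_mild = _e632plus(apparent, oob, np.array([5.0]))
    assert est_mild < est


def test_bootstrap_pec_deterministic_and_b1_works():
    rng = np.random.default_rng(4)
    outcome = random_outcome(rng, 40, ties=False)
    times = np.quantile(outcome.time[outcome.event == 1], [0.3, 0.6])
    km = km_estimator(outcome)

    def fit_predict(idx):
        sub = np.arange(outcome.n) if idx is None else idx
        sub_out = SurvivalOutcome(
            time=outcome.time[sub], event=outcome.event[sub],
            sample_ids=np.array([f"r{i}" for i in range(len(sub))], dtype=object),
        )
        return np.tile(km_estimator(sub_out)(times), (outcome.n, 1))

    c1 = bootstrap_632plus_pec(fit_predict, outcome, times, B=5, seed=9)
    c2 = bootstrap_632plus_pec(fit_predict, outcome, times, B=5, seed=9)
    np.testing.assert_array_equal(c1.e632plus, c2.e632plus)
    np.testing.assert_array_equal(c1.per_draw_integrated, c2.per_draw_integrated)
    single = bootstrap_632plus_pec(fit_predict, outcome, times, B=1, seed=9)
    assert np.isfinite(single.e632plus).all()
    assert single.per_draw_integrated.shape == (1,)


def test_bootstrap_mse_degenerate_model():
    rng = np.random.default_rng(5)
    y = rng.standard_normal(30)

    def fit_predict(idx):
        return np.zeros(30)  # fixed predictions: oob equals apparent

    res = bootstrap_632plus_mse(fit_predict, y, B=10, seed=1)
    assert res["e632plus"] == pytest.approx(res["apparent"], abs=1e-12)


def test_integrated_pec_hand_values():
    assert integrated_pec([0.0, 1.0, 2.0], [0.1, 0.3, 0.2], 2.0) == pytest.approx(0.225)
    # left-constant extension down to zero
    assert integrated_pec([1.0, 2.0], [0.4, 0.2], 2.0) == pytest.approx(0.35)
    with pytest.raises(ValueError, match="support"):
        integrated_pec([1.0, 2.0], [0.4, 0.2], 3.0)


def test_inclusion_frequencies_basics():
    ids = [f"s{i}" for i in range(30)]
    event = np.ones(30, dtype=int)

    def always_f1(sub_ids, rep_seed):
        assert len(sub_ids) == 18  # floor(0.632 * 30)
        return ["f1"]

    freqs = inclusion_frequencies(
        always_f1, ids, ["f0", "f1", "f2"], B=7, seed=0, event=event
    )
    assert freqs["f1"] == 1.0
    assert freqs["f0"] == 0.0 and freqs["f2"] == 0.0
    assert freqs.attrs["B"] == 7
    assert freqs.attrs["subsample_size"] == 18


def test_inclusion_frequencies_unknown_feature_raises():
    ids = [f"s{i}" for i in range(20)]

    def bad(sub_ids, rep_seed):
        return ["not_a_feature"]

    with pytest.raises(KeyError, match="not_a_feature"):
        inclusion_frequencies(bad, ids, ["f0"], B=1, seed=0)


def test_inclusion_frequencies_deterministic():
    ids = [f"s{i}" for i in range(25)]

    def stochastic(sub_ids, rep_seed):
        rng = np.random.default_rng(rep_seed)
        return [f"f{rng.integers(0, 4)}"]

    feats = [f"f{j}" for j in range(4)]
    f1 = inclusion_frequencies(stochastic, ids, feats, B=10, seed=3)
    f2 = inclusion_frequencies(stochastic, ids, feats, B=10, seed=3)
    pd.testing.assert_series_equal(f1, f2)


def test_clinical_benchmark_matches_lifelines():
    rng = np.random.default_rng(6)
    outcome = random_outcome(rng, 90, ties=False)
    clin = random_matrix(rng, outcome.sample_ids, 3, "c")
    fit = clinical_cox_benchmark(clin, outcome)
    df = clin.copy()
    df["time"] = outcome.time
    df["event"] = outcome.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    np.testing.assert_allclose(
        fit.mandatory_coefficients().to_numpy(),
        cph.params_.loc[fit.mandatory_ids].to_numpy(),
        atol=1e-5,
    )
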