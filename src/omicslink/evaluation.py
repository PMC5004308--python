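"""Stability and prediction-performance evaluation machinery.

Prediction performance is measured by the time-dependent Brier score with
inverse-probability-of-censoring weights (IPCW), combined over bootstrap
resamples by the .632+ estimator, against a Kaplan-Meier benchmark that uses
no covariates and an unpenalized clinical Cox model.  Selection stability is
quantified by inclusion frequencies over subsamples of size floor(0.632 n)
drawn without replacement, rerunning the entire model-building procedure
(including cross-validated step selection) in every resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sksurv.nonparametric import kaplan_meier_estimator

from .boosting import StepFunction, fit_cox_boost
from .containers import BoostConfig, BoostFit, LayeredCohort, SurvivalOutcome

__all__ = [
    "km_estimator",
    "censoring_km",
    "ipcw_weights",
    "brier_curve",
    "default_time_grid",
    "PredictionErrorCurve",
    "bootstrap_632plus_pec",
    "bootstrap_632plus_mse",
    "integrated_pec",
    "inclusion_frequencies",
    "clinical_cox_benchmark",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier machinery
# ---------------------------------------------------------------------------

def km_estimator(outcome: SurvivalOutcome) -> StepFunction:
    """Product-limit estimate of the survival function, as a right-continuous
    step function starting at 1."""
    if outcome.n == 0:
        raise ValueError("empty outcome")
    times, probs = kaplan_meier_estimator(outcome.event.astype(bool), outcome.time)
    return StepFunction(times, probs, initial=1.0)


def censoring_km(outcome: SurvivalOutcome) -> StepFunction:
    """Kaplan-Meier estimate of the censoring distribution G(t) (reverse KM),
    used for IPCW weights."""
    if outcome.n == 0:
        raise ValueError("empty outcome")
    cens = outcome.event == 0
    if not cens.any():
        # no censoring: G is identically 1
        return StepFunction(np.array([np.inf]), np.array([1.0]), initial=1.0)
    times, probs = kaplan_meier_estimator(cens, outcome.time)
    return StepFunction(times, probs, initial=1.0)


def ipcw_weights(outcome: SurvivalOutcome, times: np.ndarray) -> np.ndarray:
    """IPCW weight matrix W[i, t].

    Sample i contributes delta_i / G(t_i-) if it had the event by t, and
    1 / G(t) if still under observation at t; samples censored by t get
    weight zero.  G is the Kaplan-Meier estimate of censoring.
    """
    G = censoring_km(outcome)
    times = np.asarray(times, dtype=float)
    t_i = outcome.time[:, None]
    had_event = (outcome.event[:, None] == 1) & (t_i <= times[None, :])
    at_risk = t_i > times[None, :]
    g_left = np.asarray(G(outcome.time, left=True))[:, None]
    g_t = np.asarray(G(times))[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(had_event, 1.0 / g_left, 0.0) + np.where(at_risk, 1.0 / g_t, 0.0)
    if not np.isfinite(w).all():
        raise ValueError("IPCW weights undefined (censoring survival reached zero)")
    return w


def default_time_grid(outcome: SurvivalOutcome, quantile: float = 0.95) -> np.ndarray:
    """Unique event times up to the given quantile of follow-up."""
    cutoff = np.quantile(outcome.time, quantile)
    grid = np.unique(outcome.time[(outcome.event == 1) & (outcome.time <= cutoff)])
    if grid.size == 0:
        raise ValueError("no event times within the requested range")
    return grid


def _event_free(outcome: SurvivalOutcome, times: np.ndarray) -> np.ndarray:
    return (outcome.time[:, None] > np.asarray(times)[None, :]).astype(float)


def brier_curve(predicted_survival, outcome: SurvivalOutcome, times) -> np.ndarray:
    """IPCW-weighted Brier score at each grid time.

    ``predicted_survival`` is a samples x times matrix of S-hat(t | x_i)
    aligned with the outcome; values must lie in [0, 1].
    """
    times = np.asarray(times, dtype=float)
    if (times > outcome.time.max()).any():
        raise ValueError("evaluation times beyond the last observed time")
    S = np.asarray(predicted_survival, dtype=float)
    if S.shape != (outcome.n, times.size):
        raise ValueError("prediction matrix must be samples x times")
    if (S < -1e-9).any() or (S > 1 + 1e-9).any():
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    W = ipcw_weights(outcome, times)
    ind = _event_free(outcome, times)
    return (W * (ind - S) ** 2).mean(axis=0)


# ---------------------------------------------------------------------------
# .632+ bootstrap
# ---------------------------------------------------------------------------

@dataclass
class PredictionErrorCurve:
    """Apparent, out-of-bag and .632+ prediction error on a time grid."""

    times: np.ndarray
    apparent: np.ndarray
    oob: np.ndarray
    e632plus: np.ndarray
    label: str = ""
    n_bootstrap: int = 0
    per_draw_integrated: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "apparent": self.apparent,
                "oob": self.oob,
                "e632plus": self.e632plus,
            }
        )


def _e632plus(apparent: np.ndarray, oob: np.ndarray, noinf: np.ndarray) -> np.ndarray:
    """Efron-Tibshirani .632+ combination, elementwise.

    R, the relative overfitting rate, is (oob - apparent) / (noinf -
    apparent) clipped to [0, 1]; the weight w = .632 / (1 - .368 R) then
    moves from .632 toward 1 as overfitting grows.
    """
    apparent = np.asarray(apparent, float)
    oob = np.asarray(oob, float)
    noinf = np.asarray(noinf, float)
    denom = noinf - apparent
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(
            (oob > apparent) & (denom > 0), (oob - apparent) / denom, 0.0
        )
    R = np.clip(R, 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    return (1.0 - w) * apparent + w * oob


def _bootstrap_draws(n: int, B: int, rng: np.random.Generator, event: Optional[np.ndarray]):
    """B bootstrap index vectors (with replacement, size n); draws without
    any event are redrawn (logged)."""
    draws = []
    for b in range(B):
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if event is None or event[idx].any():
                break
            logger.info("bootstrap draw %d without events; redrawing", b)
        else:
            raise RuntimeError("could not draw a bootstrap sample containing events")
        draws.append(idx)
    return draws


def bootstrap_632plus_pec(
    fit_predict: Callable[[Optional[np.ndarray]], np.ndarray],
    outcome: SurvivalOutcome,
    times,
    B: int = 100,
    seed: int = 0,
    label: str = "",
) -> PredictionErrorCurve:
    """.632+ prediction error curve for a refittable survival model.

    ``fit_predict(indices)`` must retrain the entire model-building pipeline
    (including any cross-validated tuning) on the bootstrap sample given by
    positional ``indices`` into the evaluation cohort — or on the full cohort
    when ``indices`` is None — and return predicted survival for all
    evaluation samples on ``times`` (samples x times).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    n = outcome.n
    W = ipcw_weights(outcome, times)
    ind = _event_free(outcome, times)

    S_app = np.asarray(fit_predict(None), dtype=float)
    loss_app = W * (ind - S_app) ** 2
    apparent = loss_app.mean(axis=0)

    acc = np.zeros((n, times.size))
    count = np.zeros(n)
    draw_curves = []
    for idx in _bootstrap_draws(n, B, rng, outcome.event):
        S_b = np.asarray(fit_predict(idx), dtype=float)
        out_of_bag = np.ones(n, dtype=bool)
        out_of_bag[idx] = False
        loss = W[out_of_bag] * (ind[out_of_bag] - S_b[out_of_bag]) ** 2
        acc[out_of_bag] += loss
        count[out_of_bag] += 1
        if out_of_bag.any():
            draw_curves.append(loss.mean(axis=0))
    covered = count > 0
    if not covered.any():
        raise RuntimeError("no sample was ever out of bag; increase B")
    oob = (acc[covered] / count[covered, None]).mean(axis=0)

    # no-information error: every prediction paired with every outcome
    m1 = S_app.mean(axis=0)
    m2 = (S_app**2).mean(axis=0)
    noinf = (W * (ind - 2 * ind * m1[None, :] + m2[None, :])).mean(axis=0)

    # variability view: the .632+ estimate recomputed per single draw
    per_draw = np.array(
        [
            integrated_pec(times, _e632plus(apparent, curve, noinf), times.max())
            for curve in draw_curves
        ]
    )

    return PredictionErrorCurve(
        times=times,
        apparent=apparent,
        oob=oob,
        e632plus=_e632plus(apparent, oob, noinf),
        label=label,
        n_bootstrap=B,
        per_draw_integrated=per_draw,
    )


def bootstrap_632plus_mse(
    fit_predict: Callable[[Optional[np.ndarray]], np.ndarray],
    y: np.ndarray,
    B: int = 100,
    seed: int = 0,
) -> dict:
    """.632+ mean-squared-error estimate for a refittable continuous-response
    model (used to judge the linking model on the overlap samples)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    pred_app = np.asarray(fit_predict(None), dtype=float)
    apparent = float(((y - pred_app) ** 2).mean())

    acc = np.zeros(n)
    count = np.zeros(n)
    for idx in _bootstrap_draws(n, B, rng, None):
        pred = np.asarray(fit_predict(idx), dtype=float)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[idx] = False
        acc[oob_mask] += (y[oob_mask] - pred[oob_mask]) ** 2
        count[oob_mask] += 1
    covered = count > 0
    oob = float((acc[covered] / count[covered]).mean())
    noinf = float(((y[:, None] - pred_app[None, :]) ** 2).mean())
    est = float(_e632plus(np.array(apparent), np.array(oob), np.array(noinf)))
    return {"apparent": apparent, "oob": oob, "noinf": noinf, "e632plus": est}


def integrated_pec(times, values, t_max: float) -> float:
    """Time-averaged prediction error: trapezoidal integral over [0, t_max]
    divided by t_max.  The curve is extended as constant left of its first
    grid point and must cover t_max."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if t_max > times.max() + 1e-12:
        raise ValueError("t_max beyond the curve's support")
    keep = times <= t_max
    ts = times[keep]
    vs = values[keep]
    if ts.size == 0 or ts[0] > 0:
        ts = np.concatenate([[0.0], ts])
        vs = np.concatenate([[vs[0] if vs.size else values[0]], vs])
    if ts[-1] < t_max:
        v_end = np.interp(t_max, times, values)
        ts = np.concatenate([ts, [t_max]])
        vs = np.concatenate([vs, [v_end]])
    return float(np.trapezoid(vs, ts) / t_max)


# ---------------------------------------------------------------------------
# Inclusion frequencies
# ---------------------------------------------------------------------------

def inclusion_frequencies(
    select_fn: Callable[[np.ndarray, int], Iterable],
    sample_ids: Sequence,
    feature_ids: Sequence,
    B: int = 100,
    seed: int = 0,
    event: Optional[np.ndarray] = None,
    subsample_fraction: float = 0.632,
) -> pd.Series:
    """Selection proportion per feature over B subsamples without replacement.

    Each subsample has exactly floor(0.632 n) distinct samples; the full
    selection pipeline is rerun per subsample via ``select_fn(sub_ids,
    replicate_seed)`` which must return the ids of the selected features.
    Subsamples without events are redrawn (logged) when ``event`` is given.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sample_ids = np.asarray(sample_ids, dtype=object)
    n = sample_ids.shape[0]
    size = int(np.floor(subsample_fraction * n))
    if size < 2:
        raise ValueError("subsample size below 2")
    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=pd.Index(feature_ids, name="feature"))
    rep_seeds = rng.integers(0, 2**31 - 1, size=B)
    for b in range(B):
        for _ in range(100):
            pos = rng.choice(n, size=size, replace=False)
            if event is None or event[pos].any():
                break
            logger.info("subsample %d without events; redrawing", b)
        else:
            raise RuntimeError("could not draw a subsample containing events")
        selected = list(select_fn(sample_ids[pos], int(rep_seeds[b])))
        unknown = [f for f in selected if f not in counts.index]
        if unknown:
            raise KeyError(f"selected features outside the feature universe: {unknown[:5]}")
        counts.loc[selected] += 1.0
    freqs = counts / B
    freqs.attrs["B"] = B
    freqs.attrs["subsample_size"] = size
    return freqs


# ---------------------------------------------------------------------------
# Clinical Cox benchmark
# ---------------------------------------------------------------------------

def clinical_cox_benchmark(
    clinical: pd.DataFrame, outcome: SurvivalOutcome
) -> BoostFit:
    """Unpenalized Cox model on the clinical covariates only (Breslow
    baseline), the conventional covariate-using benchmark."""
    return fit_cox_boost(
        mandatory=clinical,
        optional=None,
        outcome=outcome,
        config=BoostConfig(n_steps_max=0, cv_folds=2),
        select_step=0,
    )
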