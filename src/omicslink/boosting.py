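"""Componentwise likelihood-based boosting for Cox and Gaussian regression.

The estimator starts from all-zero coefficients and, at every boosting step,
evaluates a penalized one-parameter update for each optional covariate given
the current fit (carried as an offset), then commits the single update whose
resulting unpenalized (partial) log-likelihood is largest.  Mandatory
covariates (e.g. established clinical predictors) are refit by standard
unpenalized maximum (partial) likelihood after every step, so their effects
are always fully adjusted for.  A fixed per-sample offset enters the linear
predictor additively and is never re-estimated, which is what allows a
first-level molecular signature to guide a second-level model.

The number of boosting steps is the main tuning parameter and is selected by
stratified k-fold cross-validation (held-out partial log-likelihood in the
Cox case, following Verweij & van Houwelingen; held-out squared error in the
Gaussian case).  The penalty on the one-parameter updates only sets the
effective step size (default shrinkage factor ~0.1 per update).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import BoostConfig, BoostFit, SurvivalOutcome, validate_design_matrix

__all__ = [
    "fit_cox_boost",
    "fit_gaussian_boost",
    "cv_select_steps",
    "predict_linear_predictor",
    "predict_survival",
    "breslow_cumulative_hazard",
    "cox_partial_loglik",
]

_EMPTY = np.zeros((0,))


# ---------------------------------------------------------------------------
# Cox partial-likelihood machinery (Breslow tie handling)
# ---------------------------------------------------------------------------

class _CoxStructure:
    """Pre-sorted survival data with tie groups for risk-set aggregation.

    Samples are sorted by observed time ascending; the risk set of sample i
    is then a suffix starting at the first member of i's tie group, so all
    risk-set sums reduce to reverse cumulative sums.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.order = order
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.group_start = np.searchsorted(self.time, self.time, side="left")
        self.ev_idx = np.nonzero(self.event)[0]
        self.ev_group = self.group_start[self.ev_idx]
        self.n = time.shape[0]
        self.n_events = self.ev_idx.shape[0]


def _revcumsum(x: np.ndarray) -> np.ndarray:
    return np.cumsum(x[::-1], axis=0)[::-1]


def _partial_loglik(eta_sorted: np.ndarray, struct: _CoxStructure) -> float:
    """Breslow partial log-likelihood; invariant to constant shifts of eta."""
    c = eta_sorted.max() if eta_sorted.size else 0.0
    w = np.exp(eta_sorted - c)
    s0 = _revcumsum(w)[struct.ev_group]
    return float(eta_sorted[struct.ev_idx].sum() - np.log(s0).sum() - struct.n_events * c)


def cox_partial_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Public Breslow partial log-likelihood of a linear predictor."""
    struct = _CoxStructure(np.asarray(time, float), np.asarray(event, int))
    return _partial_loglik(np.asarray(eta, float)[struct.order], struct)


def _cox_scores(eta_sorted: np.ndarray, Z_sorted: np.ndarray, struct: _CoxStructure):
    """Per-covariate score and Fisher information at coefficient zero.

    Returns (U, I) for every column of Z given the current linear predictor.
    """
    c = eta_sorted.max()
    w = np.exp(eta_sorted - c)
    s0 = _revcumsum(w)[struct.ev_group]
    wz = w[:, None] * Z_sorted
    s1 = _revcumsum(wz)[struct.ev_group]
    s2 = _revcumsum(wz * Z_sorted)[struct.ev_group]
    mu = s1 / s0[:, None]
    U = (Z_sorted[struct.ev_idx] - mu).sum(axis=0)
    I = (s2 / s0[:, None] - mu * mu).sum(axis=0)
    return U, I


def _candidate_logliks(
    eta_sorted: np.ndarray, Z_sorted: np.ndarray, delta: np.ndarray, struct: _CoxStructure
) -> np.ndarray:
    """Partial log-likelihood after applying each column's candidate update."""
    shift = eta_sorted[:, None] + delta[None, :] * Z_sorted
    c = shift.max(axis=0)
    w = np.exp(shift - c[None, :])
    s0 = _revcumsum(w)[struct.ev_group]
    ev_lin = eta_sorted[struct.ev_idx].sum() + delta * Z_sorted[struct.ev_idx].sum(axis=0)
    return ev_lin - np.log(s0).sum(axis=0) - struct.n_events * c


def _cox_mandatory_gradient(eta_sorted, Xm_sorted, struct):
    """Score vector and observed information matrix for the mandatory block."""
    c = eta_sorted.max()
    w = np.exp(eta_sorted - c)
    s0 = _revcumsum(w)[struct.ev_group]
    wx = w[:, None] * Xm_sorted
    s1 = _revcumsum(wx)[struct.ev_group]
    mu = s1 / s0[:, None]
    U = (Xm_sorted[struct.ev_idx] - mu).sum(axis=0)
    outer = w[:, None, None] * Xm_sorted[:, :, None] * Xm_sorted[:, None, :]
    s2 = _revcumsum(outer)[struct.ev_group]
    H = (s2 / s0[:, None, None]).sum(axis=0) - mu.T @ mu
    return U, H


def _cox_newton(
    Xm_sorted: np.ndarray,
    fixed_eta_sorted: np.ndarray,
    struct: _CoxStructure,
    alpha0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> np.ndarray:
    """Unpenalized Newton maximization of the Cox partial likelihood over the
    mandatory block, with the rest of the fit held fixed as an offset."""
    if Xm_sorted.shape[1] == 0:
        return alpha0
    alpha = alpha0.copy()
    pl = _partial_loglik(fixed_eta_sorted + Xm_sorted @ alpha, struct)
    for _ in range(max_iter):
        eta = fixed_eta_sorted + Xm_sorted @ alpha
        U, H = _cox_mandatory_gradient(eta, Xm_sorted, struct)
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design in mandatory covariates") from exc
        # step halving keeps Newton monotone on awkward data
        for _ in range(30):
            cand = alpha + step
            pl_new = _partial_loglik(fixed_eta_sorted + Xm_sorted @ cand, struct)
            if pl_new >= pl - 1e-12:
                break
            step = step / 2.0
        alpha = cand
        if np.abs(step).max() < tol or abs(pl_new - pl) < 1e-12:
            pl = pl_new
            break
        pl = pl_new
    return alpha


# ---------------------------------------------------------------------------
# Standardization helpers
# ---------------------------------------------------------------------------

class _Standardizer:
    """Center mandatory covariates; center+scale optional covariates.

    All boosting updates happen on the standardized scale; reported
    coefficients are mapped back to the original covariate scale.  Constant
    optional covariates are zeroed out internally and can never be selected.
    """

    def __init__(self, Xm: np.ndarray, Xo: np.ndarray):
        self.mu_m = Xm.mean(axis=0) if Xm.shape[1] else np.zeros(0)
        self.mu_o = Xo.mean(axis=0) if Xo.shape[1] else np.zeros(0)
        sd = Xo.std(axis=0) if Xo.shape[1] else np.zeros(0)
        self.constant = sd == 0
        self.scale = np.where(self.constant, 1.0, sd)
        self.Xm_c = Xm - self.mu_m
        Z = (Xo - self.mu_o) / self.scale
        if self.constant.any():
            Z[:, self.constant] = 0.0
        self.Z = Z

    def coef_to_raw(self, gamma_std_path: np.ndarray) -> np.ndarray:
        return gamma_std_path / self.scale


def _raw_eta_path(
    Xm: np.ndarray,
    Xo: np.ndarray,
    offset: np.ndarray,
    mandatory_path: np.ndarray,
    coef_path_raw: np.ndarray,
) -> np.ndarray:
    """Per-step linear predictor on the raw covariate scale, offset included."""
    eta = np.tile(offset, (mandatory_path.shape[0], 1))
    if Xm.shape[1]:
        eta += mandatory_path @ Xm.T
    if Xo.shape[1]:
        eta += coef_path_raw @ Xo.T
    return eta


# ---------------------------------------------------------------------------
# Path fitting
# ---------------------------------------------------------------------------

def _cox_boost_path(Xm, Xo, time, event, offset, penalty, n_steps):
    """Core Cox boosting path on numpy arrays.

    Returns (coef_path_raw, mandatory_path, criterion_path) where the
    criterion is the in-sample partial log-likelihood after each step.
    """
    n, q = Xo.shape
    d = Xm.shape[1]
    struct = _CoxStructure(time, event)
    std = _Standardizer(Xm, Xo)
    Zs = std.Z[struct.order]
    Xms = std.Xm_c[struct.order]
    offs = offset[struct.order]

    gamma = np.zeros(q)
    coef_path = np.zeros((n_steps + 1, q))
    mandatory_path = np.zeros((n_steps + 1, d))
    criterion = np.zeros(n_steps + 1)

    eta_opt = np.zeros(n)
    alpha = _cox_newton(Xms, offs + eta_opt, struct, np.zeros(d))
    mandatory_path[0] = alpha
    criterion[0] = _partial_loglik(offs + eta_opt + (Xms @ alpha if d else 0.0), struct)

    for m in range(1, n_steps + 1):
        eta = offs + eta_opt + (Xms @ alpha if d else 0.0)
        if q:
            U, I = _cox_scores(eta, Zs, struct)
            delta = U / (I + penalty)
            delta[std.constant] = 0.0
            pl_cand = _candidate_logliks(eta, Zs, delta, struct)
            pl_cand[std.constant] = -np.inf
            j = int(np.argmax(pl_cand))
            gamma[j] += delta[j]
            eta_opt = eta_opt + delta[j] * Zs[:, j]
        alpha = _cox_newton(Xms, offs + eta_opt, struct, alpha)
        coef_path[m] = gamma
        mandatory_path[m] = alpha
        criterion[m] = _partial_loglik(offs + eta_opt + (Xms @ alpha if d else 0.0), struct)

    return std.coef_to_raw(coef_path), mandatory_path, criterion


def _gaussian_boost_path(Xm, Xo, y, offset, penalty, n_steps):
    """Componentwise penalized least-squares boosting path.

    Intercept and mandatory coefficients are refit by OLS after every step.
    Returns (coef_path_raw, mandatory_path, intercept_path_raw, rss_path).
    """
    n, q = Xo.shape
    d = Xm.shape[1]
    std = _Standardizer(Xm, Xo)
    Z = std.Z
    design_m = np.column_stack([np.ones(n), std.Xm_c])
    # pseudo-inverse reused at every refit; rank-deficient mandatory designs
    # (possible on very small samples) get the minimum-norm least-squares fit
    pinv_m = np.linalg.pinv(design_m)
    if d and np.linalg.matrix_rank(design_m) < d + 1:
        warnings.warn(
            "rank-deficient mandatory design; using minimum-norm least squares",
            UserWarning,
            stacklevel=2,
        )

    ztz = (Z * Z).sum(axis=0)
    gamma = np.zeros(q)
    coef_path = np.zeros((n_steps + 1, q))
    mandatory_path = np.zeros((n_steps + 1, d))
    intercept_path = np.zeros(n_steps + 1)
    rss = np.zeros(n_steps + 1)

    y_adj = y - offset
    fit_opt = np.zeros(n)

    def refit_mandatory():
        coefs = pinv_m @ (y_adj - fit_opt)
        return coefs[0], coefs[1:]

    b0, alpha = refit_mandatory()
    intercept_path[0] = b0
    mandatory_path[0] = alpha
    resid = y_adj - fit_opt - design_m @ np.concatenate([[b0], alpha])
    rss[0] = float(resid @ resid)

    for m in range(1, n_steps + 1):
        if q:
            u = Z.T @ resid
            denom = ztz + penalty
            delta = np.where(std.constant, 0.0, u / np.where(denom > 0, denom, 1.0))
            # RSS reduction of each candidate update
            gain = 2.0 * delta * u - delta * delta * ztz
            gain[std.constant] = -np.inf
            j = int(np.argmax(gain))
            gamma[j] += delta[j]
            fit_opt = fit_opt + delta[j] * Z[:, j]
        b0, alpha = refit_mandatory()
        resid = y_adj - fit_opt - design_m @ np.concatenate([[b0], alpha])
        coef_path[m] = gamma
        mandatory_path[m] = alpha
        intercept_path[m] = b0
        rss[m] = float(resid @ resid)

    coef_raw = std.coef_to_raw(coef_path)
    # put the intercept on the raw covariate scale so that
    # y_hat = intercept + Xm @ alpha + Xo @ gamma + offset
    intercept_raw = (
        intercept_path
        - coef_raw @ std.mu_o
        - (mandatory_path @ std.mu_m if d else 0.0)
    )
    return coef_raw, mandatory_path, intercept_raw, rss


# ---------------------------------------------------------------------------
# Cross-validated step selection
# ---------------------------------------------------------------------------

def _stratified_folds(n: int, strata: Optional[np.ndarray], n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    for value in np.unique(strata):
        idx = np.nonzero(strata == value)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def cv_select_steps(
    family: str,
    Xm: np.ndarray,
    Xo: np.ndarray,
    offset: np.ndarray,
    config: BoostConfig,
    outcome: Optional[SurvivalOutcome] = None,
    response: Optional[np.ndarray] = None,
    penalty: Optional[float] = None,
):
    """Choose the number of boosting steps by k-fold cross-validation.

    Cox: maximizes the summed held-out partial log-likelihood, computed per
    fold as pl(all samples) - pl(training samples) under the fold's fit.
    Gaussian: minimizes the mean held-out squared prediction error.
    Fold assignment is a deterministic function of ``config.seed`` and is
    stratified by event status for the Cox family.  Ties are broken toward
    the smaller step.  Returns (selected_step, cv_score_per_grid_step).
    """
    grid = config.resolved_grid()
    if grid.size == 1:
        return int(grid[0]), np.zeros(1)
    if config.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2 for cross-validation")

    n = Xm.shape[0] if Xm.shape[1] else Xo.shape[0]
    n_folds = min(config.cv_folds, n)
    n_steps = int(grid.max())

    if family == "cox":
        assert outcome is not None
        if outcome.n_events < n_folds:
            raise ValueError(
                f"only {outcome.n_events} events for {n_folds}-fold CV; "
                "every fold must contain events"
            )
        folds = _stratified_folds(n, outcome.event, n_folds, config.seed)
        struct_all = _CoxStructure(outcome.time, outcome.event)
        scores = np.zeros(grid.size)
        for k in range(n_folds):
            train = folds != k
            coef, mand, _ = _cox_boost_path(
                Xm[train], Xo[train], outcome.time[train], outcome.event[train],
                offset[train], penalty, n_steps,
            )
            eta_all = _raw_eta_path(Xm, Xo, offset, mand, coef)
            struct_tr = _CoxStructure(outcome.time[train], outcome.event[train])
            for gi, step in enumerate(grid):
                pl_all = _partial_loglik(eta_all[step][struct_all.order], struct_all)
                pl_tr = _partial_loglik(eta_all[step][train][struct_tr.order], struct_tr)
                scores[gi] += pl_all - pl_tr
        best = int(grid[int(np.argmax(scores))])
        return best, scores

    if family == "gaussian":
        assert response is not None
        folds = _stratified_folds(n, None, n_folds, config.seed)
        scores = np.zeros(grid.size)
        for k in range(n_folds):
            train = folds != k
            test = ~train
            coef, mand, icpt, _ = _gaussian_boost_path(
                Xm[train], Xo[train], response[train], offset[train], penalty, n_steps
            )
            pred = _raw_eta_path(Xm[test], Xo[test], offset[test], mand, coef) + icpt[:, None]
            err = ((pred - response[test][None, :]) ** 2).mean(axis=1)
            scores += err[grid]
        best = int(grid[int(np.argmin(scores))])
        return best, scores

    raise ValueError(f"unknown family: {family}")


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def _align_inputs(mandatory, optional, sample_ids, offset):
    ids = list(sample_ids)
    frames = []
    for df, name in ((mandatory, "mandatory"), (optional, "optional")):
        if df is None:
            df = pd.DataFrame(index=pd.Index(ids))
        validate_design_matrix(df, name)
        missing = [s for s in ids if s not in df.index]
        if missing:
            raise ValueError(f"{name} matrix lacks samples: {missing[:5]}")
        frames.append(df.loc[ids])
    mandatory, optional = frames
    n = len(ids)
    if offset is None:
        off = np.zeros(n)
    elif isinstance(offset, pd.Series):
        missing = [s for s in ids if s not in offset.index]
        if missing:
            raise ValueError(f"offset lacks samples: {missing[:5]}")
        off = offset.loc[ids].to_numpy(dtype=float)
    else:
        off = np.asarray(offset, dtype=float)
        if off.shape != (n,):
            raise ValueError("offset length must equal the number of samples")
    if not np.isfinite(off).all():
        raise ValueError("offset contains non-finite values")
    return mandatory, optional, off


def _resolve_step(select_step, config, cv_fn):
    if isinstance(select_step, (int, np.integer)):
        step = int(select_step)
        if not 0 <= step <= config.n_steps_max:
            raise ValueError("requested step outside 0..n_steps_max")
        return step, None
    if select_step == "last":
        return config.n_steps_max, None
    if select_step == "cv":
        return cv_fn()
    raise ValueError("select_step must be 'cv', 'last' or an integer")


def fit_cox_boost(
    mandatory: Optional[pd.DataFrame],
    optional: Optional[pd.DataFrame],
    outcome: SurvivalOutcome,
    offset=None,
    config: Optional[BoostConfig] = None,
    select_step: Union[str, int] = "cv",
) -> BoostFit:
    """Fit a Cox proportional-hazards model by componentwise boosting.

    ``mandatory`` covariates are refit unpenalized at every step; ``optional``
    covariates compete for one penalized update per step.  ``offset`` is a
    per-sample term with coefficient fixed at one (e.g. a first-level
    signature).  With ``select_step='cv'`` the returned fit's
    ``selected_step`` is chosen by cross-validation on ``config.step_grid``.
    """
    config = config or BoostConfig()
    if outcome.n_events == 0:
        raise ValueError("no events: Cox model cannot be fit")
    mandatory, optional, off = _align_inputs(mandatory, optional, outcome.sample_ids, offset)
    Xm = mandatory.to_numpy(dtype=float)
    Xo = optional.to_numpy(dtype=float)
    penalty = config.penalty if config.penalty is not None else 9.0 * outcome.n_events

    def _cv():
        return cv_select_steps(
            "cox", Xm, Xo, off, config, outcome=outcome, penalty=penalty
        )

    if select_step == "cv":
        step, cv_scores = _cv()
    else:
        step, _ = _resolve_step(select_step, config, _cv)
        cv_scores = None

    coef, mand, crit = _cox_boost_path(
        Xm, Xo, outcome.time, outcome.event, off, penalty, config.n_steps_max
    )
    eta_path = _raw_eta_path(Xm, Xo, off, mand, coef)
    return BoostFit(
        family="cox",
        feature_ids=list(optional.columns),
        mandatory_ids=list(mandatory.columns),
        coef_path=coef,
        mandatory_path=mand,
        selected_step=int(step),
        offset=off,
        sample_ids=np.asarray(outcome.sample_ids, dtype=object),
        train_criterion_path=crit,
        eta_path=eta_path,
        outcome=outcome,
        cv_scores=cv_scores,
        config=config,
    )


def fit_gaussian_boost(
    mandatory: Optional[pd.DataFrame],
    optional: Optional[pd.DataFrame],
    response,
    sample_ids: Optional[Sequence] = None,
    offset=None,
    config: Optional[BoostConfig] = None,
    select_step: Union[str, int] = "cv",
) -> BoostFit:
    """Fit a Gaussian linear model by componentwise penalized least-squares
    boosting, with intercept and mandatory covariates refit unpenalized."""
    config = config or BoostConfig()
    if isinstance(response, pd.Series):
        if sample_ids is None:
            sample_ids = list(response.index)
        y = response.loc[list(sample_ids)].to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        if sample_ids is None:
            src = mandatory if mandatory is not None else optional
            if src is None:
                raise ValueError("sample_ids required when no matrix is given")
            sample_ids = list(src.index)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    mandatory, optional, off = _align_inputs(mandatory, optional, sample_ids, offset)
    Xm = mandatory.to_numpy(dtype=float)
    Xo = optional.to_numpy(dtype=float)
    n = y.shape[0]
    # unit-variance internal scaling makes z'z = n, so 9n gives shrinkage 0.1
    penalty = config.penalty if config.penalty is not None else 9.0 * n

    def _cv():
        return cv_select_steps(
            "gaussian", Xm, Xo, off, config, response=y, penalty=penalty
        )

    if select_step == "cv":
        step, cv_scores = _cv()
    else:
        step, _ = _resolve_step(select_step, config, _cv)
        cv_scores = None

    coef, mand, icpt, rss = _gaussian_boost_path(Xm, Xo, y, off, penalty, config.n_steps_max)
    eta_path = _raw_eta_path(Xm, Xo, off, mand, coef) + icpt[:, None]
    return BoostFit(
        family="gaussian",
        feature_ids=list(optional.columns),
        mandatory_ids=list(mandatory.columns),
        coef_path=coef,
        mandatory_path=mand,
        selected_step=int(step),
        offset=off,
        sample_ids=np.asarray(list(sample_ids), dtype=object),
        train_criterion_path=rss,
        eta_path=eta_path,
        intercept_path=icpt,
        response=y,
        cv_scores=cv_scores,
        config=config,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_linear_predictor(
    fit: BoostFit,
    mandatory: Optional[pd.DataFrame] = None,
    optional: Optional[pd.DataFrame] = None,
    at_step: Optional[int] = None,
    offset=None,
) -> pd.Series:
    """Linear predictor (mandatory + optional + offset contributions, plus the
    intercept for the Gaussian family) for new samples at a path step."""
    step = fit.selected_step if at_step is None else int(at_step)
    if not 0 <= step <= fit.n_steps:
        raise ValueError(f"step {step} outside fitted range 0..{fit.n_steps}")
    frames = []
    for df, ids, name in (
        (mandatory, fit.mandatory_ids, "mandatory"),
        (optional, fit.feature_ids, "optional"),
    ):
        if ids:
            if df is None:
                raise ValueError(f"{name} covariates required for prediction")
            missing = [f for f in ids if f not in df.columns]
            if missing:
                raise ValueError(f"missing {name} feature columns: {missing[:5]}")
            frames.append(df[ids])
        else:
            frames.append(None)
    mand_df, opt_df = frames
    for df in (mand_df, opt_df, mandatory, optional):
        if df is not None:
            index = df.index
            break
    else:
        if isinstance(offset, pd.Series):
            index = offset.index
        else:
            raise ValueError("cannot infer sample index: no covariates or indexed offset given")
    n = len(index)
    eta = np.zeros(n)
    if mand_df is not None:
        eta += mand_df.to_numpy(dtype=float) @ fit.mandatory_path[step]
    if opt_df is not None:
        eta += opt_df.to_numpy(dtype=float) @ fit.coef_path[step]
    if offset is not None:
        off = offset.loc[index].to_numpy(float) if isinstance(offset, pd.Series) else np.asarray(offset, float)
        eta += off
    if fit.intercept_path is not None:
        eta += fit.intercept_path[step]
    return pd.Series(eta, index=index)


class StepFunction:
    """Right-continuous step function with optional left limits."""

    def __init__(self, x: np.ndarray, y: np.ndarray, initial: float = 0.0):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.initial = initial

    def __call__(self, t, left: bool = False):
        t = np.asarray(t, dtype=float)
        side = "left" if left else "right"
        idx = np.searchsorted(self.x, t, side=side) - 1
        out = np.where(idx < 0, self.initial, self.y[np.clip(idx, 0, len(self.y) - 1)])
        return out if out.ndim else float(out)


def breslow_cumulative_hazard(outcome: SurvivalOutcome, eta: np.ndarray) -> StepFunction:
    """Breslow estimator of the cumulative baseline hazard for linear
    predictor ``eta`` on the training samples."""
    eta = np.asarray(eta, dtype=float)
    struct = _CoxStructure(outcome.time, outcome.event)
    center = eta.mean()
    w = np.exp(eta[struct.order] - center)  # centered for numerical stability
    s0 = _revcumsum(w)
    ev_times = struct.time[struct.ev_idx]
    uniq, counts = np.unique(ev_times, return_counts=True)
    pos = np.searchsorted(struct.time, uniq, side="left")
    increments = counts * np.exp(-center) / s0[pos]
    return StepFunction(uniq, np.cumsum(increments), initial=0.0)


def predict_survival(
    fit: BoostFit,
    mandatory: Optional[pd.DataFrame] = None,
    optional: Optional[pd.DataFrame] = None,
    times=None,
    at_step: Optional[int] = None,
    offset=None,
) -> pd.DataFrame:
    """Predicted survival S(t|x) = exp(-H0(t) exp(eta)) on a time grid.

    The baseline cumulative hazard is the Breslow estimate from the training
    data at the same path step; beyond the last training event time the
    hazard is extrapolated as constant.
    """
    if fit.family != "cox":
        raise ValueError("survival prediction requires a Cox fit")
    if fit.outcome is None:
        raise ValueError("fit carries no training outcome")
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    step = fit.selected_step if at_step is None else int(at_step)
    base = breslow_cumulative_hazard(fit.outcome, fit.eta_path[step])
    eta = predict_linear_predictor(fit, mandatory, optional, at_step=step, offset=offset)
    h0 = base(times)
    center = float(fit.eta_path[step].mean())
    surv = np.exp(-np.outer(np.exp(eta.to_numpy() - center), h0 * np.exp(center)))
    return pd.DataFrame(surv, index=eta.index, columns=times)
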