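"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit loops and naive risk-set
enumeration, deliberately sharing no code with the package internals.
"""

import numpy as np


def naive_partial_loglik(eta, time, event):
    """Breslow partial log-likelihood by explicit risk-set enumeration."""
    pl = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            pl += eta[i] - np.log(sum(np.exp(eta[j]) for j in risk))
    return pl


def naive_cox_score_info(eta, x, time, event):
    """Score and Fisher information of one covariate at coefficient zero."""
    U = 0.0
    I = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            w = np.array([np.exp(eta[j]) for j in risk])
            xr = np.array([x[j] for j in risk])
            s0 = w.sum()
            mean = (w * xr).sum() / s0
            U += x[i] - mean
            I += (w * xr**2).sum() / s0 - mean**2
    return U, I


def naive_newton_cox(Xm, fixed_eta, time, event, max_iter=200, tol=1e-12):
    """Unpenalized Cox MLE for the mandatory block by damped Newton with
    numerically-differenced scores (slow, small problems only)."""
    d = Xm.shape[1]
    alpha = np.zeros(d)

    def pl(a):
        return naive_partial_loglik(fixed_eta + Xm @ a, time, event)

    h = 1e-5
    for _ in range(max_iter):
        grad = np.zeros(d)
        hess = np.zeros((d, d))
        for a_idx in range(d):
            e = np.zeros(d)
            e[a_idx] = h
            grad[a_idx] = (pl(alpha + e) - pl(alpha - e)) / (2 * h)
        for a_idx in range(d):
            for b_idx in range(d):
                ea, eb = np.zeros(d), np.zeros(d)
                ea[a_idx] = h
                eb[b_idx] = h
                hess[a_idx, b_idx] = (
                    pl(alpha + ea + eb) - pl(alpha + ea - eb)
                    - pl(alpha - ea + eb) + pl(alpha - ea - eb)
                ) / (4 * h * h)
        step = np.linalg.solve(-hess, grad)
        base = pl(alpha)
        scale = 1.0
        for _ in range(40):
            if pl(alpha + scale * step) >= base - 1e-13:
                break
            scale /= 2
        alpha = alpha + scale * step
        if np.abs(scale * step).max() < tol:
            break
    return alpha


def naive_cox_boost(Xm, Xo, time, event, offset, penalty, n_steps):
    """Brute-force componentwise Cox boosting.

    At each step, for every optional covariate (standardized), computes the
    penalized one-parameter update from the naive score/information, then
    evaluates the naive partial log-likelihood after each candidate update;
    the covariate with the largest resulting log-likelihood is updated
    (ties to the lowest index).  The mandatory block is refit by naive
    Newton after every step.  Returns paths on the original covariate scale.
    """
    n, q = Xo.shape
    mu = Xo.mean(axis=0)
    sd = Xo.std(axis=0)
    scale = np.where(sd == 0, 1.0, sd)
    Z = (Xo - mu) / scale
    Z[:, sd == 0] = 0.0
    Xm_c = Xm - Xm.mean(axis=0) if Xm.shape[1] else Xm

    gamma = np.zeros(q)
    path = np.zeros((n_steps + 1, q))
    mand = np.zeros((n_steps + 1, Xm.shape[1]))
    chosen = []

    alpha = naive_newton_cox(Xm_c, offset + Z @ gamma, time, event) if Xm.shape[1] else np.zeros(0)
    mand[0] = alpha
    for m in range(1, n_steps + 1):
        eta = offset + Z @ gamma + (Xm_c @ alpha if Xm.shape[1] else 0.0)
        best_j, best_pl, best_delta = None, -np.inf, 0.0
        for j in range(q):
            if sd[j] == 0:
                continue
            U, I = naive_cox_score_info(eta, Z[:, j], time, event)
            delta = U / (I + penalty)
            cand_pl = naive_partial_loglik(eta + delta * Z[:, j], time, event)
            if cand_pl > best_pl:
                best_j, best_pl, best_delta = j, cand_pl, delta
        gamma[best_j] += best_delta
        chosen.append(best_j)
        if Xm.shape[1]:
            alpha = naive_newton_cox(Xm_c, offset + Z @ gamma, time, event)
        path[m] = gamma / scale
        mand[m] = alpha
    return path, mand, chosen


def naive_gaussian_boost(Xm, Xo, y, penalty, n_steps):
    """Brute-force componentwise Gaussian boosting with per-step OLS refit of
    intercept and mandatory covariates.  Returns (path_raw, chosen)."""
    n, q = Xo.shape
    mu = Xo.mean(axis=0)
    sd = Xo.std(axis=0)
    scale = np.where(sd == 0, 1.0, sd)
    Z = (Xo - mu) / scale
    Z[:, sd == 0] = 0.0
    D = np.column_stack([np.ones(n), Xm - Xm.mean(axis=0)]) if Xm.shape[1] else np.ones((n, 1))

    gamma = np.zeros(q)
    path = np.zeros((n_steps + 1, q))
    chosen = []
    for m in range(1, n_steps + 1):
        coefs, *_ = np.linalg.lstsq(D, y - Z @ gamma, rcond=None)
        resid = y - Z @ gamma - D @ coefs
        best_j, best_rss, best_delta = None, np.inf, 0.0
        for j in range(q):
            if sd[j] == 0:
                continue
            zj = Z[:, j]
            delta = (zj @ resid) / (zj @ zj + penalty)
            rss = ((resid - delta * zj) ** 2).sum()
            if rss < best_rss - 1e-15:
                best_j, best_rss, best_delta = j, rss, delta
        gamma[best_j] += best_delta
        chosen.append(best_j)
        path[m] = gamma / scale
    return path, chosen


def naive_brier(surv_matrix, time, event, eval_times):
    """IPCW Brier score with an explicitly looped reverse Kaplan-Meier."""

    def km_censoring(t, left=False):
        # product-limit over censoring events, explicit loop
        uniq = np.unique(time)
        g = 1.0
        for s in uniq:
            if (s < t) if left else (s <= t):
                at_risk = (time >= s).sum()
                cens_here = ((time == s) & (event == 0)).sum()
                g *= 1.0 - cens_here / at_risk
        return g

    out = []
    n = len(time)
    for k, t in enumerate(eval_times):
        total = 0.0
        for i in range(n):
            if time[i] <= t and event[i] == 1:
                w = 1.0 / km_censoring(time[i], left=True)
                total += w * (0.0 - surv_matrix[i, k]) ** 2
            elif time[i] > t:
                w = 1.0 / km_censoring(t)
                total += w * (1.0 - surv_matrix[i, k]) ** 2
        out.append(total / n)
    return np.array(out)
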