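"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes a different computational route from the code
it checks: dense grid search instead of gradient optimization, exhaustive
sign-pattern enumeration instead of the normal approximation, direct
numerical maximization of the correlation instead of the whitened SVD, and
per-subset least-squares fits instead of correlation-matrix algebra.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LinearRegression


def harm_grid_nll(records, kappa_step: float = 0.01, betas=(0.5, 1, 2, 5, 10, 20)):
    """Best NLL over a dense (κ, β) grid, per condition, summed."""
    kappas = np.arange(0.0, 1.0 + kappa_step / 2, kappa_step)
    total = 0.0
    for cond in ("self", "other"):
        dm = np.array([r.trial.d_money for r in records if r.trial.beneficiary == cond])
        ds = np.array([r.trial.d_shocks for r in records if r.trial.beneficiary == cond])
        y = np.array(
            [1.0 if r.choice == "harmful" else 0.0 for r in records if r.trial.beneficiary == cond]
        )
        best = np.inf
        for beta in betas:
            dv = (1.0 - kappas[:, None]) * dm[None, :] - kappas[:, None] * ds[None, :]
            p = expit(beta * dv)
            p_obs = np.where(y[None, :] == 1.0, p, 1.0 - p)
            nll = -np.sum(np.log(np.maximum(p_obs, 1e-12)), axis=1)
            best = min(best, float(nll.min()))
        total += best
    return total


def effort_grid_nll(records, lambda_step: float = 0.005, betas=(0.5, 1, 2, 5, 10)):
    """Best NLL over a dense (λ_self, λ_other, β) grid with shared β."""
    lams = np.arange(0.0, 0.5 + lambda_step / 2, lambda_step)
    cond_nll = {}
    for cond in ("self", "other"):
        recs = [r for r in records if not r.missed and r.trial.beneficiary == cond]
        R = np.array([r.trial.reward for r in recs], dtype=float)
        E = np.array([r.trial.effort_units for r in recs])
        y = np.array([1.0 if r.choice == "work" else 0.0 for r in recs])
        per_beta = []
        for beta in betas:
            sv = R[None, :] - lams[:, None] * E[None, :] ** 2
            p = expit(beta * (sv - 1.0))
            p_obs = np.where(y[None, :] == 1.0, p, 1.0 - p)
            per_beta.append(-np.sum(np.log(np.maximum(p_obs, 1e-12)), axis=1))
        cond_nll[cond] = np.array(per_beta)  # (n_beta, n_lambda)
    # shared beta: minimize over lambda pairs within each beta, then over beta
    best = np.inf
    for b in range(len(betas)):
        best = min(best, float(cond_nll["self"][b].min() + cond_nll["other"][b].min()))
    return best


def wilcoxon_enumeration(diffs):
    """Exact signed-rank null by enumerating all sign patterns.

    Returns (W_observed, z from exact null moments, exact two-sided p).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    w_all = np.array(
        [ranks[np.array(signs, dtype=bool)].sum() for signs in itertools.product([0, 1], repeat=n)]
    )
    mu, sigma = w_all.mean(), w_all.std(ddof=0)
    z = (w_obs - mu) / sigma
    tail = min(np.mean(w_all >= w_obs), np.mean(w_all <= w_obs))
    return w_obs, z, min(1.0, 2.0 * tail)


def cca_first_corr_bruteforce(X, Y, n_restarts: int = 20, seed: int = 0):
    """Maximize corr(Xa, Yb) directly over coefficient vectors."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    p, q = Xc.shape[1], Yc.shape[1]
    rng = np.random.default_rng(seed)

    def neg_corr(v):
        a, b = v[:p], v[p:]
        u, w = Xc @ a, Yc @ b
        denom = np.linalg.norm(u) * np.linalg.norm(w)
        if denom < 1e-12:
            return 0.0
        return -abs(float(u @ w) / denom)

    best = 0.0
    for _ in range(n_restarts):
        v0 = rng.standard_normal(p + q)
        res = minimize(neg_corr, v0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        best = max(best, -float(res.fun))
    return best


def commonality_regression_oracle(X, y):
    """Unique/common/total per predictor via explicit least-squares fits."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    k = X.shape[1]

    def r2(cols):
        if not cols:
            return 0.0
        return float(LinearRegression().fit(X[:, cols], y).score(X[:, cols], y))

    full = r2(list(range(k)))
    out = []
    for j in range(k):
        total = float(np.corrcoef(X[:, j], y)[0, 1] ** 2)
        unique = full - r2([i for i in range(k) if i != j])
        out.append((unique, total - unique, total))
    return np.array(out)
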