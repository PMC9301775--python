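"""Canonical correlation analysis with permutation inference and commonality
variance partitioning.

The CCA relates a p-variable set X (here 18 trait scores) to a q-variable
set Y (here the two prosociality indices).  Both sets are z-scored (n−1
denominator); the solution comes from the SVD of the doubly whitened
cross-correlation matrix R_xx^{-1/2} R_xy R_yy^{-1/2}, whose singular values
are the canonical correlations and whose singular vectors, back-transformed
through the whiteners, give standardized canonical weights.  Structure
coefficients (loadings) are correlations of each observed variable with its
own canonical variate; cross-loadings — correlations with the opposite
variate — satisfy cross = loading × r_k exactly.

Sequential significance uses Wilks' Λ with Rao's F approximation; a
distribution-free alternative permutes the rows of Y and uses Roy's largest
root (the largest squared canonical correlation) as the test statistic.
Commonality analysis decomposes the variance in a criterion explained by a
predictor subset into each predictor's unique contribution (R² drop when it
is removed) and its common contribution (total minus unique; negative values
flag suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ROLE_CONTRIBUTOR = "contributor"
ROLE_COLLINEAR = "collinear-contributor"
ROLE_SUPPRESSOR = "suppressor-candidate"
ROLE_NEGLIGIBLE = "negligible"


@dataclass(frozen=True)
class CCAResult:
    correlations: np.ndarray  # (k,)
    x_weights: np.ndarray  # (p, k) standardized function coefficients
    y_weights: np.ndarray  # (q, k)
    x_loadings: np.ndarray  # (p, k) structure coefficients
    y_loadings: np.ndarray  # (q, k)
    x_cross_loadings: np.ndarray  # (p, k)
    y_cross_loadings: np.ndarray  # (q, k)
    x_scores: np.ndarray  # (n, k) canonical variates, unit variance
    y_scores: np.ndarray  # (n, k)
    wilks: pd.DataFrame  # per-function lambda, F, df1, df2, p
    x_names: tuple
    y_names: tuple
    n: int


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    statistic: float  # observed largest squared canonical correlation
    null: np.ndarray  # permutation distribution of the statistic


def _zscore(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column(s)")
    return (M - M.mean(axis=0)) / sd


def _names(M, prefix: str) -> tuple:
    if isinstance(M, pd.DataFrame):
        return tuple(M.columns)
    return tuple(f"{prefix}{j}" for j in range(np.asarray(M).shape[1]))


def _inv_sqrt(R: np.ndarray, names: tuple, tol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root; errors naming near-dependent columns."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < tol:
        bad = vecs[:, vals < tol]
        implicated = np.unique(np.abs(bad).argmax(axis=0))
        cols = [names[j] for j in implicated]
        raise ValueError(f"rank-deficient set; columns implicated: {cols}")
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def fit_cca(X, Y, y_sign_anchor: int = 0) -> "CCAResult":
    """Fit a CCA between two multivariate sets.

    Columns are z-scored internally.  Each canonical function's sign is
    flipped, if needed, so the Y-loading of column ``y_sign_anchor``
    (hyperaltruism in the trait analysis) is non-negative.
    """
    x_names, y_names = _names(X, "x"), _names(Y, "y")
    Xz, Yz = _zscore(np.asarray(X, dtype=float)), _zscore(np.asarray(Y, dtype=float))
    n, p = Xz.shape
    q = Yz.shape[1]
    if Yz.shape[0] != n:
        raise ValueError("X and Y need the same number of rows")
    if n <= p + q:
        raise ValueError("need n > p + q observations")

    Rxx = Xz.T @ Xz / (n - 1)
    Ryy = Yz.T @ Yz / (n - 1)
    Rxy = Xz.T @ Yz / (n - 1)
    Wx = _inv_sqrt(Rxx, x_names)
    Wy = _inv_sqrt(Ryy, y_names)
    U, s, Vt = np.linalg.svd(Wx @ Rxy @ Wy)
    k = min(p, q)
    r = np.clip(s[:k], 0.0, 1.0)
    A = Wx @ U[:, :k]  # standardized weights: Var(Xz @ A) = I
    B = Wy @ Vt.T[:, :k]

    y_load = Ryy @ B
    flip = np.where(y_load[y_sign_anchor, :] < 0, -1.0, 1.0)
    A *= flip
    B *= flip

    x_load = Rxx @ A
    y_load = Ryy @ B
    result = CCAResult(
        correlations=r,
        x_weights=A,
        y_weights=B,
        x_loadings=x_load,
        y_loadings=y_load,
        x_cross_loadings=x_load * r[None, :],
        y_cross_loadings=y_load * r[None, :],
        x_scores=Xz @ A,
        y_scores=Yz @ B,
        wilks=wilks_sequential_test(r, n, p, q),
        x_names=x_names,
        y_names=y_names,
        n=n,
    )
    return result


def wilks_sequential_test(r_list, n: int, p: int, q: int) -> pd.DataFrame:
    """Sequential Wilks'-Λ tests of canonical functions via Rao's F.

    For function k, Λ_k = Π_{i≥k}(1−r_i²) tests that function k and all
    later ones are null; Rao's approximation gives F(df1, df2) with
    df1 = p_k·q_k and df2 = m·s − p_k·q_k/2 + 1, where p_k = p−k+1,
    q_k = q−k+1, m = n − 3/2 − (p+q)/2 and s the standard Rao exponent.
    """
    r = np.asarray(r_list, dtype=float)
    if np.any(np.diff(r) > 1e-12):
        raise ValueError("canonical correlations must be sorted descending")
    rows = []
    one_minus = 1.0 - r**2
    for k in range(1, len(r) + 1):
        lam = float(np.prod(one_minus[k - 1 :]))
        pk, qk = p - k + 1, q - k + 1
        df1 = pk * qk
        denom = pk**2 + qk**2 - 5
        s = np.sqrt((pk**2 * qk**2 - 4) / denom) if denom > 0 else 1.0
        m = n - 1.5 - (p + q) / 2.0
        df2 = m * s - df1 / 2.0 + 1.0
        if lam <= 0:
            f_stat, p_val = np.inf, 0.0
        else:
            ratio = lam ** (1.0 / s)
            f_stat = (1.0 - ratio) / ratio * df2 / df1
            p_val = float(sps.f.sf(f_stat, df1, df2))
        rows.append(
            {"function": k, "wilks_lambda": lam, "F": float(f_stat),
             "df1": float(df1), "df2": float(df2), "p": p_val}
        )
    return pd.DataFrame(rows)


def _largest_sq_canonical_corr(Xw: np.ndarray, Yw: np.ndarray, n: int) -> float:
    s = np.linalg.svd(Xw.T @ Yw / (n - 1), compute_uv=False)
    return float(min(s[0], 1.0) ** 2)


def permutation_test(
    X, Y, n_perm: int = 1000, seed: int | None = None
) -> PermutationResult:
    """Roy's-largest-root permutation test of the first canonical correlation.

    Rows of Y are permuted jointly (within-set structure intact); the p-value
    is (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    Xz = _zscore(np.asarray(X, dtype=float))
    Yz = _zscore(np.asarray(Y, dtype=float))
    n = Xz.shape[0]
    Xw = Xz @ _inv_sqrt(Xz.T @ Xz / (n - 1), _names(X, "x"))
    Yw = Yz @ _inv_sqrt(Yz.T @ Yz / (n - 1), _names(Y, "y"))
    observed = _largest_sq_canonical_corr(Xw, Yw, n)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _largest_sq_canonical_corr(Xw, Yw[rng.permutation(n)], n)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(float(p), observed, null)


def commonality(X_sub, criterion) -> pd.DataFrame:
    """Unique/common/total variance partition of a criterion over predictors.

    For each predictor j: total_j is its squared zero-order correlation with
    the criterion, unique_j = R²(all) − R²(all minus j), and
    common_j = total_j − unique_j (negative common flags suppression).
    In the trait analysis the criterion is the opposite-set (prosocial)
    canonical variate of function 1.
    """
    names = _names(X_sub, "x")
    X = np.asarray(X_sub, dtype=float)
    if X.shape[1] > 20:
        raise ValueError("more than 20 predictors: all-subsets partition infeasible")
    y = np.asarray(criterion, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("criterion length must match predictors")
    Z = _zscore(X)
    yz = (y - y.mean()) / y.std(ddof=1)
    n = Z.shape[0]
    R = Z.T @ Z / (n - 1)
    r_yc = Z.T @ yz / (n - 1)

    def r2(idx):
        if len(idx) == 0:
            return 0.0
        sub = np.ix_(idx, idx)
        return float(r_yc[idx] @ np.linalg.solve(R[sub], r_yc[idx]))

    k = Z.shape[1]
    full = r2(list(range(k)))
    rows = []
    for j in range(k):
        total = float(r_yc[j] ** 2)
        unique = full - r2([i for i in range(k) if i != j])
        rows.append(
            {"variable": names[j], "unique": unique, "common": total - unique,
             "total": total}
        )
    return pd.DataFrame(rows)


def classify_roles(
    loadings, weights, cross_loadings=None, threshold: float = 0.3
) -> list[str]:
    """Label variables on one canonical function by loading/weight pattern.

    High loading + high weight → contributor; high loading + low weight →
    collinear contributor (variance carried by other variables); low loading
    + high weight → suppressor candidate; otherwise negligible.
    """
    loadings = np.asarray(loadings, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if loadings.shape != weights.shape:
        raise ValueError("loadings and weights must align")
    roles = []
    for ld, w in zip(loadings, weights):
        high_l, high_w = abs(ld) >= threshold, abs(w) >= threshold
        if high_l and high_w:
            roles.append(ROLE_CONTRIBUTOR)
        elif high_l:
            roles.append(ROLE_COLLINEAR)
        elif high_w:
            roles.append(ROLE_SUPPRESSOR)
        else:
            roles.append(ROLE_NEGLIGIBLE)
    return roles


def select_commonality_predictors(
    loadings, weights, threshold: float = 0.3
) -> np.ndarray:
    """Indices of variables with |loading| ≥ threshold or |weight| ≥ threshold."""
    loadings = np.asarray(loadings, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    return np.flatnonzero(
        (np.abs(loadings) >= threshold) | (np.abs(weights) >= threshold)
    )
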