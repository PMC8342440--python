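"""Canonical correlation analysis on PCA bases, variable loadings, and
age association of the first canonical axis with bootstrap inference.

The CCA maximizes ``corr(a' E1, b' E2)`` over weight vectors a, b; it is
solved by SVD of the whitened cross-covariance (QR whitening), which is
equivalent to the generalized eigenvalue formulation and numerically
stable.  Loadings are reconstructed as Pearson correlations between the
original normalized variables and the factor scores.  The age association
of the first canonical pair is the square root of the R^2 of an OLS of age
on the two first-factor score columns; significance comes from a
resampling test that breaks the pairing between factors and age, and the
standard error from a joint resampling of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import SubjectFeatureTable

__all__ = [
    "CcaModel",
    "AgeAxisFit",
    "fit_cca",
    "compute_loadings",
    "age_correlation",
    "bootstrap_null_p",
    "bootstrap_se",
    "cca_permutation_null",
]


@dataclass
class CcaModel:
    weights_a: np.ndarray       # (n_comp1, n_factors)
    weights_b: np.ndarray       # (n_comp2, n_factors)
    factors_F1: np.ndarray      # (n_subjects, n_factors)
    factors_F2: np.ndarray
    canonical_corrs: np.ndarray
    mean_E1: np.ndarray         # training column means used for centering
    mean_E2: np.ndarray
    loadings_L1: np.ndarray | None = None
    loadings_L2: np.ndarray | None = None

    @property
    def n_factors(self) -> int:
        return self.weights_a.shape[1]

    def project(self, E1: np.ndarray | None = None, E2: np.ndarray | None = None):
        """Apply trained centering and weights to new component scores."""
        F1 = None if E1 is None else (np.asarray(E1) - self.mean_E1) @ self.weights_a
        F2 = None if E2 is None else (np.asarray(E2) - self.mean_E2) @ self.weights_b
        return F1, F2


@dataclass
class AgeAxisFit:
    w1: float
    w2: float
    intercept: float
    r_age: float
    p_value: float | None = None
    se: float | None = None
    boot_mean: float | None = None


def fit_cca(E1: np.ndarray, E2: np.ndarray, orient_to: np.ndarray | None = None) -> CcaModel:
    """Fit a standard CCA between two score matrices.

    Factor pairs are ordered by decreasing canonical correlation.  Signs
    are fixed deterministically: each pair is flipped so the largest-|.|
    element of its E2-side weight vector is positive; if ``orient_to``
    (e.g. age) is given, the first pair is instead oriented so both factor
    columns correlate non-negatively with it.
    """
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    if E1.shape[0] != E2.shape[0]:
        raise ValueError("subject counts differ between bases")
    n = E1.shape[0]
    m1 = E1.mean(axis=0)
    m2 = E2.mean(axis=0)
    X = E1 - m1
    Y = E2 - m2
    Qx, Rx = np.linalg.qr(X)
    Qy, Ry = np.linalg.qr(Y)
    for R, name in ((Rx, "E1"), (Ry, "E2")):
        if np.abs(np.diag(R)).min() < 1e-10 * max(1.0, np.abs(np.diag(R)).max()):
            raise ValueError(f"{name} is rank deficient")
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    k = min(X.shape[1], Y.shape[1])
    U, s, V = U[:, :k], np.clip(s[:k], 0.0, 1.0), Vt[:k].T
    a = np.linalg.solve(Rx, U * np.sqrt(n - 1))
    b = np.linalg.solve(Ry, V * np.sqrt(n - 1))
    F1 = X @ a
    F2 = Y @ b

    # deterministic sign convention
    for j in range(k):
        col = b[:, j]
        sign = np.sign(col[np.argmax(np.abs(col))])
        if sign == 0:
            sign = 1.0
        a[:, j] *= sign
        b[:, j] *= sign
        F1[:, j] *= sign
        F2[:, j] *= sign
    if orient_to is not None:
        y = np.asarray(orient_to, dtype=float)
        c = np.corrcoef(F1[:, 0] + F2[:, 0], y)[0, 1]
        if c < 0:
            a[:, 0] *= -1; b[:, 0] *= -1; F1[:, 0] *= -1; F2[:, 0] *= -1
    return CcaModel(
        weights_a=a, weights_b=b, factors_F1=F1, factors_F2=F2,
        canonical_corrs=s, mean_E1=m1, mean_E2=m2,
    )


def compute_loadings(D: SubjectFeatureTable | pd.DataFrame | np.ndarray, F: np.ndarray) -> np.ndarray:
    """Loadings L[v, k] = Pearson correlation of variable v with factor k.

    Missing cells are excluded pairwise; factor columns must be non-constant.
    """
    if isinstance(D, SubjectFeatureTable):
        D = D.values
    if isinstance(D, pd.DataFrame):
        vals = D.to_numpy(dtype=float)
    else:
        vals = np.asarray(D, dtype=float)
    F = np.asarray(F, dtype=float)
    if vals.shape[0] != F.shape[0]:
        raise ValueError("subject counts differ between data and factors")
    if np.any(F.std(axis=0) == 0):
        raise ValueError("zero-variance factor column")
    nvar, nfac = vals.shape[1], F.shape[1]
    L = np.empty((nvar, nfac))
    for v in range(nvar):
        col = vals[:, v]
        ok = np.isfinite(col)
        x = col[ok]
        if x.std() == 0:
            raise ValueError(f"zero-variance variable at column {v}")
        xc = x - x.mean()
        Fc = F[ok] - F[ok].mean(axis=0)
        L[v] = (xc @ Fc) / (np.sqrt(xc @ xc) * np.sqrt((Fc**2).sum(axis=0)))
    return L


def _r_from_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of y on [X | 1]; returns (coefficients incl. intercept, sqrt(R^2))."""
    n = len(y)
    A = np.column_stack([X, np.ones(n)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("outcome has zero variance")
    r2 = max(0.0, 1.0 - float(resid @ resid) / tss)
    return beta, float(np.sqrt(r2))


def age_correlation(F1_col: np.ndarray, F2_col: np.ndarray, age: np.ndarray) -> AgeAxisFit:
    """r_age = sqrt(R^2) of OLS: age ~ w1 F1 + w2 F2 + b (reported unsigned)."""
    F1_col = np.asarray(F1_col, float).ravel()
    F2_col = np.asarray(F2_col, float).ravel()
    age = np.asarray(age, float).ravel()
    if not (len(F1_col) == len(F2_col) == len(age)):
        raise ValueError("length mismatch")
    if len(age) < 4:
        raise ValueError("need at least 4 subjects")
    X = np.column_stack([F1_col, F2_col])
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance regressor")
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(age))])) < 3:
        raise ValueError("collinear regressors")
    beta, r = _r_from_ols(X, age)
    return AgeAxisFit(w1=float(beta[0]), w2=float(beta[1]), intercept=float(beta[2]), r_age=r)


def _batched_r(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """sqrt(R^2) for many OLS problems at once.

    Xb: (B, n, p) regressors, yb: (B, n) outcomes; intercept added.
    """
    B, n, p = Xb.shape
    ones = np.ones((B, n, 1))
    A = np.concatenate([Xb, ones], axis=2)
    AtA = np.einsum("bni,bnj->bij", A, A)
    Aty = np.einsum("bni,bn->bi", A, yb)
    beta = np.linalg.solve(AtA, Aty[..., None])[..., 0]
    fit = np.einsum("bni,bi->bn", A, beta)
    resid = yb - fit
    rss = (resid**2).sum(axis=1)
    tss = ((yb - yb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    r2 = np.clip(1.0 - rss / tss, 0.0, 1.0)
    return np.sqrt(r2)


def bootstrap_null_p(
    x_cols: np.ndarray, y: np.ndarray, n_boot: int = 10000, seed: int = 0,
    permute: bool = False, batch: int = 2000,
) -> float:
    """One-sided significance of r_age against a no-association null.

    Each replicate resamples the rows of the regressor columns with
    replacement (or permutes them, with ``permute=True``), breaking their
    pairing with ``y``, and recomputes sqrt(R^2).  p is the fraction of
    null replicates at or above the observed value.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(x_cols, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    _, r_obs = _r_from_ols(X, y)
    count = 0
    done = 0
    while done < n_boot:
        b = min(batch, n_boot - done)
        if permute:
            idx = np.stack([rng.permutation(n) for _ in range(b)])
        else:
            idx = rng.integers(0, n, size=(b, n))
        r_null = _batched_r(X[idx], np.broadcast_to(y, (b, n)))
        count += int((r_null >= r_obs).sum())
        done += b
    return count / n_boot


def bootstrap_se(
    x_cols: np.ndarray, y: np.ndarray, n_boot: int = 10000, seed: int = 0,
    batch: int = 2000,
) -> tuple[float, float]:
    """Bootstrap mean and SE of r_age: subjects (rows of X and y) resampled jointly."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(x_cols, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    rs = []
    done = 0
    while done < n_boot:
        b = min(batch, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        rs.append(_batched_r(X[idx], y[idx]))
        done += b
    rs = np.concatenate(rs)
    return float(rs.mean()), float(rs.std(ddof=1))


def cca_permutation_null(
    E1: np.ndarray, E2: np.ndarray, n_perm: int = 200, seed: int = 0
) -> np.ndarray:
    """Null distribution of the first canonical correlation: permute the
    subject rows of E2 relative to E1 and refit.  Returns the n_perm rho_1
    samples (used to judge whether an observed rho_1 exceeds chance)."""
    rng = np.random.default_rng(seed)
    E1 = np.asarray(E1, float)
    E2 = np.asarray(E2, float)
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = fit_cca(E1, E2[rng.permutation(len(E2))]).canonical_corrs[0]
    return out
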