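"""Data normalization ahead of the CCA: quality filtering, z-scoring,
nuisance deconfounding, nearest-SPD covariance rotation and PCA.

The fixed pipeline order is filter -> z-score -> deconfound ->
(behavior only: nearest-SPD covariance rotation) -> PCA.  Missing cells
survive z-scoring and deconfounding as missing; they are imputed at the
variable mean (0 after standardization) only where a complete matrix is
required (regression design, PCA scores), while covariances use
pairwise-complete statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import ConfoundTable, SubjectFeatureTable

__all__ = [
    "PcaBasis",
    "filter_variables",
    "zscore",
    "ZscoreStats",
    "deconfound",
    "DeconfoundModel",
    "nearest_spd_covariance",
    "pca_basis",
    "behavior_pipeline",
]


@dataclass
class PcaBasis:
    components: np.ndarray         # (n_variables, n_comp), orthonormal columns
    scores: np.ndarray             # (n_subjects, n_comp)
    explained_variance: np.ndarray
    variable_ids: list[str]


@dataclass
class ZscoreStats:
    mean: pd.Series
    sd: pd.Series


@dataclass
class DeconfoundModel:
    """OLS coefficients per variable for the [intercept | confounds | extra] design."""
    beta: np.ndarray               # (n_regressors, n_variables)
    design_columns: list[str]
    conf_mean: np.ndarray
    conf_sd: np.ndarray


def filter_variables(
    table: SubjectFeatureTable, outlier_sd: float = 3.0, min_presence: float = 0.5
) -> tuple[SubjectFeatureTable, pd.DataFrame]:
    """Drop variables with extreme outliers or excessive missingness.

    A variable is removed if any observed cell lies more than ``outlier_sd``
    sample standard deviations from the variable's own mean, or if its
    missing fraction is at least ``min_presence``.  The removal report lists
    each dropped variable with the triggering reason and statistic.
    """
    df = table.values
    if df.shape[1] == 0:
        raise ValueError("empty feature table")
    removals = []
    keep = []
    miss_frac = df.isna().mean(axis=0)
    z = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
    max_abs_z = z.abs().max(axis=0)
    for var in df.columns:
        if miss_frac[var] >= min_presence:
            removals.append((var, "missingness", float(miss_frac[var])))
        elif df[var].std(ddof=1) == 0 or not np.isfinite(max_abs_z[var]):
            removals.append((var, "constant", 0.0))
        elif max_abs_z[var] > outlier_sd:
            removals.append((var, "outlier", float(max_abs_z[var])))
        else:
            keep.append(var)
    if not keep:
        raise ValueError("all variables removed by filtering")
    report = pd.DataFrame(removals, columns=["variable", "reason", "statistic"])
    out = SubjectFeatureTable(df[keep].copy(), table.variable_domains[keep].copy())
    return out, report


def zscore(
    table: SubjectFeatureTable, stats: ZscoreStats | None = None
) -> tuple[SubjectFeatureTable, ZscoreStats]:
    """Standardize each variable over its observed cells (sample-SD convention).

    When ``stats`` is given (hold-out projection), those training means/SDs
    are applied instead of recomputing.  Missing cells stay missing.
    """
    df = table.values
    if stats is None:
        mean = df.mean(axis=0)
        sd = df.std(axis=0, ddof=1)
        bad = sd[(sd == 0) | ~np.isfinite(sd)]
        if len(bad):
            raise ValueError(f"zero-variance variables: {list(bad.index)}")
        stats = ZscoreStats(mean=mean, sd=sd)
    z = (df - stats.mean) / stats.sd
    return SubjectFeatureTable(z, table.variable_domains.copy()), stats


def _design_matrix(
    confounds: ConfoundTable | pd.DataFrame | None,
    extra: np.ndarray | None,
    n_subjects: int,
    model: DeconfoundModel | None,
) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(n_subjects)], ["intercept"]
    if confounds is not None:
        cdf = confounds.values if isinstance(confounds, ConfoundTable) else confounds
        c = cdf.to_numpy(dtype=float)
        if model is None:
            cm, cs = c.mean(axis=0), c.std(axis=0, ddof=1)
        else:
            cm, cs = model.conf_mean[: c.shape[1]], model.conf_sd[: c.shape[1]]
        cs = np.where(cs == 0, 1.0, cs)
        cols.append((c - cm) / cs)
        names += list(cdf.columns)
    else:
        cm = np.array([])
        cs = np.array([])
    if extra is not None:
        e = np.asarray(extra, dtype=float).reshape(n_subjects, -1)
        if model is None:
            em, es = e.mean(axis=0), e.std(axis=0, ddof=1)
        else:
            em = model.conf_mean[len(cm):]
            es = model.conf_sd[len(cs):]
        es = np.where(es == 0, 1.0, es)
        cols.append((e - em) / es)
        names += [f"extra_{i}" for i in range(e.shape[1])]
        cm = np.concatenate([cm, em])
        cs = np.concatenate([cs, es])
    X = np.column_stack(cols)
    return X, names, cm, cs


def deconfound(
    table: SubjectFeatureTable,
    confounds: ConfoundTable | pd.DataFrame | None,
    extra: np.ndarray | None = None,
    model: DeconfoundModel | None = None,
) -> tuple[SubjectFeatureTable, DeconfoundModel]:
    """Replace each variable by its OLS residual on [intercept | confounds | extra].

    Missing cells are imputed at the variable mean (0 after z-scoring) for
    the regression fit and restored to missing in the output.  Passing a
    fitted ``model`` applies training coefficients to new subjects instead
    of refitting (hold-out projection).
    """
    df = table.values
    n = len(df)
    X, names, cm, cs = _design_matrix(confounds, extra, n, model)
    if model is None:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient confound design")
        Y = df.fillna(0.0).to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        model = DeconfoundModel(beta=beta, design_columns=names, conf_mean=cm, conf_sd=cs)
    resid = df.to_numpy(dtype=float) - X @ model.beta
    out = pd.DataFrame(resid, index=df.index, columns=df.columns).where(df.notna())
    return SubjectFeatureTable(out, table.variable_domains.copy()), model


def nearest_spd_covariance(
    table_or_cov: SubjectFeatureTable | np.ndarray,
    eig_floor: float = 1e-10,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> np.ndarray:
    """Frobenius-nearest symmetric positive-definite covariance.

    Starts from the pairwise-complete covariance (well-defined under
    missingness but not guaranteed PSD) and applies Higham-style
    alternating projections between the symmetric matrices and the cone of
    matrices with eigenvalues >= ``eig_floor``.  An already-SPD input is a
    fixed point and is returned unchanged.
    """
    if isinstance(table_or_cov, SubjectFeatureTable):
        if table_or_cov.values.shape[1] < 2:
            raise ValueError("need at least 2 variables for a covariance")
        A = table_or_cov.values.cov(min_periods=1).to_numpy()
        if np.isnan(A).any():
            raise ValueError("covariance undefined: some variable pairs share no subjects")
    else:
        A = np.asarray(table_or_cov, dtype=float)
    A = (A + A.T) / 2.0
    Y, ds = A.copy(), np.zeros_like(A)
    for _ in range(max_iter):
        R = Y - ds
        w, V = np.linalg.eigh((R + R.T) / 2.0)
        X = (V * np.maximum(w, eig_floor)) @ V.T
        ds = X - R
        Y_new = (X + X.T) / 2.0
        delta = np.linalg.norm(Y_new - Y, "fro") / max(np.linalg.norm(Y, "fro"), 1.0)
        Y = Y_new
        if delta < tol and np.linalg.eigvalsh(Y).min() >= eig_floor * 0.5:
            return Y
    w = np.linalg.eigvalsh(Y)
    if w.min() >= eig_floor * 0.5:
        return Y
    raise RuntimeError(
        f"nearest-SPD projection did not converge: min eigenvalue {w.min():.3e} "
        f"after {max_iter} iterations"
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|.| element of each column positive."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def pca_basis(
    table: SubjectFeatureTable,
    n_comp: int,
    covariance: np.ndarray | None = None,
) -> PcaBasis:
    """Eigendecomposition PCA with a fixed sign convention.

    With ``covariance`` given (the behavior branch), components are
    eigenvectors of that matrix and scores are the zero-imputed
    standardized data projected on them.  Otherwise the sample covariance
    of the (zero-imputed) data is decomposed — standard PCA, since the
    data are already centered by z-scoring.
    """
    df = table.values
    n, m = df.shape
    if not (1 <= n_comp <= min(n, m)):
        raise ValueError(f"n_comp={n_comp} out of range for {n}x{m} data")
    Z = df.fillna(0.0).to_numpy(dtype=float)
    C = covariance if covariance is not None else np.cov(Z, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_comp]
    comps = _fix_signs(V[:, order])
    return PcaBasis(
        components=comps,
        scores=Z @ comps,
        explained_variance=w[order],
        variable_ids=list(df.columns),
    )


def behavior_pipeline(
    table: SubjectFeatureTable,
    confounds: ConfoundTable | pd.DataFrame | None,
    n_comp: int,
    extra: np.ndarray | None = None,
    outlier_sd: float = 3.0,
    min_presence: float = 0.5,
    spd: bool = True,
    do_filter: bool = True,
    prefit: dict | None = None,
) -> dict:
    """Full branch preprocessing: filter -> z-score -> deconfound ->
    (optional nearest-SPD covariance) -> PCA.  Returns all fitted statistics
    so the identical transform can be replayed on hold-out subjects via
    ``prefit``.  ``spd=False`` gives the network branch (plain PCA);
    ``do_filter=False`` skips quality filtering (cross-validation folds,
    where the variable set is fixed once on the full sample).
    """
    if prefit is None:
        if do_filter:
            filtered, report = filter_variables(table, outlier_sd, min_presence)
        else:
            filtered, report = table, pd.DataFrame(columns=["variable", "reason", "statistic"])
        z, stats = zscore(filtered)
        resid, model = deconfound(z, confounds, extra=extra)
        cov = nearest_spd_covariance(resid) if spd else None
        basis = pca_basis(resid, n_comp, covariance=cov)
        return {
            "kept": filtered.variable_ids, "report": report, "zstats": stats,
            "deconf": model, "cov": cov, "basis": basis, "table": resid,
        }
    sub = SubjectFeatureTable(
        table.values[prefit["kept"]].copy(), table.variable_domains[prefit["kept"]].copy()
    )
    z, _ = zscore(sub, stats=prefit["zstats"])
    resid, _ = deconfound(z, confounds, extra=extra, model=prefit["deconf"])
    scores = resid.values.fillna(0.0).to_numpy() @ prefit["basis"].components
    return {"table": resid, "scores": scores}
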