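"""Repeated k-fold cross-validation of the PCA-CCA model and the
PCA-dimension grid search scored by the age correlation of the first
canonical axis.

Every repeat re-partitions the subjects at random into k near-equal folds;
each fold is hold-out-projected through preprocessing statistics, PCA
components and CCA weights fitted on the remaining folds, so every subject
receives exactly one hold-out factor estimate per repeat.  Fold models are
sign/order-aligned to a full-data reference model before accumulation
(canonical factors have arbitrary sign and may permute between fits), and
the final estimate for every factor score and loading is the element-wise
median across repeats with the across-repeat SD as its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cca import CcaModel, age_correlation, compute_loadings, fit_cca
from .prep import behavior_pipeline
from .synthdata import ConfoundTable, SubjectFeatureTable

__all__ = [
    "TrainedTwoView",
    "CrossValResult",
    "GridSearchResult",
    "fit_two_view",
    "holdout_project",
    "repeated_kfold_cca",
    "grid_search",
    "grid_plan",
]


@dataclass
class TrainedTwoView:
    """Preprocessing statistics + PCA bases + CCA weights from one training set."""

    prep1: dict
    prep2: dict
    model: CcaModel
    n_comp_pair: tuple[int, int]
    deconfound_age: bool


@dataclass
class CrossValResult:
    holdout_F1: np.ndarray        # (n_subjects, n_factors) medians across repeats
    holdout_F2: np.ndarray
    holdout_F1_se: np.ndarray
    holdout_F2_se: np.ndarray
    holdout_L1: np.ndarray        # (n_vars1, n_factors) medians
    holdout_L2: np.ndarray
    holdout_L1_se: np.ndarray
    holdout_L2_se: np.ndarray
    rho_median: np.ndarray        # per-axis hold-out canonical correlation
    rho_se: np.ndarray
    r_age_median: float
    r_age_se: float
    rho1_repeats: np.ndarray
    r_age_repeats: np.ndarray
    n_repeats: int
    k: int
    seed: int


@dataclass
class GridSearchResult:
    grid: pd.DataFrame            # columns: p_brain, p_behavior, r_age_median, r_age_se
    best_pair: tuple[int, int]
    n_cells: int
    n_models_total: int           # cells x CV throws


def _subset(table: SubjectFeatureTable, idx: np.ndarray) -> SubjectFeatureTable:
    return SubjectFeatureTable(table.values.iloc[idx], table.variable_domains)


def _subset_conf(conf, idx):
    if conf is None:
        return None
    df = conf.values if isinstance(conf, ConfoundTable) else conf
    return df.iloc[idx]


def fit_two_view(
    D1: SubjectFeatureTable,
    D2: SubjectFeatureTable,
    confounds: ConfoundTable | pd.DataFrame | None,
    n_comp_pair: tuple[int, int],
    age: np.ndarray | None = None,
    deconfound_age: bool = False,
    orient_to: np.ndarray | None = None,
    do_filter: bool = False,
    spd_pair: tuple[bool, bool] = (True, False),
) -> TrainedTwoView:
    """Fit both preprocessing branches and the CCA on one training sample.

    ``D1`` is the behavior-style branch (nearest-SPD rotation before PCA by
    default), ``D2`` the network-style branch (plain PCA).  With
    ``deconfound_age=True`` the subjects' age joins the nuisance design of
    both branches before PCA (the age-deconfounded model variant).
    """
    extra = None
    if deconfound_age:
        if age is None:
            raise ValueError("deconfound_age=True requires age")
        extra = np.asarray(age, float).reshape(-1, 1)
    p1 = behavior_pipeline(D1, confounds, n_comp_pair[0], extra=extra,
                           spd=spd_pair[0], do_filter=do_filter)
    p2 = behavior_pipeline(D2, confounds, n_comp_pair[1], extra=extra,
                           spd=spd_pair[1], do_filter=do_filter)
    model = fit_cca(p1["basis"].scores, p2["basis"].scores, orient_to=orient_to)
    return TrainedTwoView(p1, p2, model, n_comp_pair, deconfound_age)


def holdout_project(
    trained: TrainedTwoView,
    D1_test: SubjectFeatureTable,
    D2_test: SubjectFeatureTable,
    conf_test: ConfoundTable | pd.DataFrame | None,
    age_test: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project held-out subjects with training statistics only.

    Test data are standardized with training means/SDs, deconfounded with
    training regression coefficients, projected on training PCA components
    and combined with training CCA weights.  No statistic is recomputed on
    the test data.
    """
    extra = None
    if trained.deconfound_age:
        if age_test is None:
            raise ValueError("trained model deconfounds age: age_test required")
        extra = np.asarray(age_test, float).reshape(-1, 1)
    missing1 = set(trained.prep1["kept"]) - set(D1_test.values.columns)
    missing2 = set(trained.prep2["kept"]) - set(D2_test.values.columns)
    if missing1 or missing2:
        raise ValueError(f"variable mismatch between train and test: {missing1 | missing2}")
    s1 = behavior_pipeline(D1_test, conf_test, trained.n_comp_pair[0], extra=extra,
                           prefit=trained.prep1)
    s2 = behavior_pipeline(D2_test, conf_test, trained.n_comp_pair[1], extra=extra,
                           prefit=trained.prep2)
    F1, F2 = trained.model.project(s1["scores"], s2["scores"])
    return F1, F2


def _variable_space_weights(trained: "TrainedTwoView") -> np.ndarray:
    """Stacked canonical weight vectors mapped back to variable space.

    Fold models get their own PCA bases (component signs and noise-subspace
    rotations are not stable across subsamples), so weight vectors are only
    comparable across fits after composing with the components.
    """
    wa = trained.prep1["basis"].components @ trained.model.weights_a
    wb = trained.prep2["basis"].components @ trained.model.weights_b
    return np.vstack([wa, wb])


def _align_to_reference(trained: "TrainedTwoView", ref: "TrainedTwoView") -> tuple[np.ndarray, np.ndarray]:
    """Greedy factor matching to a reference model by |cosine| of stacked
    variable-space weight vectors; returns (permutation, signs) to apply to
    the fold's factor columns so they line up with the reference's."""
    W = _variable_space_weights(trained)
    Wr = _variable_space_weights(ref)
    k = W.shape[1]
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    Wrn = Wr / np.linalg.norm(Wr, axis=0, keepdims=True)
    C = Wn.T @ Wrn  # cosine(model col, ref col)
    perm = np.full(k, -1)
    signs = np.ones(k)
    absC = np.abs(C.copy())
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(absC), absC.shape)
        perm[j] = i
        signs[j] = 1.0 if C[i, j] >= 0 else -1.0
        absC[i, :] = -1.0
        absC[:, j] = -1.0
    return perm, signs


def _fold_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if f < rem else 0) for f in range(k)]


def repeated_kfold_cca(
    D1: SubjectFeatureTable,
    D2: SubjectFeatureTable,
    age: np.ndarray,
    confounds: ConfoundTable | pd.DataFrame | None = None,
    k: int = 5,
    n_repeats: int = 100,
    n_comp_pair: tuple[int, int] = (3, 3),
    seed: int = 0,
    deconfound_age: bool = False,
) -> CrossValResult:
    """Repeated k-fold cross-validation of the two-view PCA-CCA model.

    Hold-out loadings are computed per repeat by correlating the
    reference-normalized data columns with the assembled full hold-out
    factor matrix (loadings are correlations over all subjects, so per-fold
    sample sizes would be too small).
    """
    n = D1.n_subjects
    if n < 2 * k:
        raise ValueError("need at least 2k subjects")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if min(_fold_sizes(n, k)) < max(n_comp_pair):
        raise ValueError("fold smaller than the number of PCA components")
    age = np.asarray(age, float).ravel()

    reference = fit_two_view(D1, D2, confounds, n_comp_pair, age=age,
                             deconfound_age=deconfound_age, orient_to=age)
    ref_D1 = reference.prep1["table"]
    ref_D2 = reference.prep2["table"]
    nfac = reference.model.n_factors

    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    F1_all = np.empty((n_repeats, n, nfac))
    F2_all = np.empty((n_repeats, n, nfac))
    L1_all = np.empty((n_repeats, ref_D1.values.shape[1], nfac))
    L2_all = np.empty((n_repeats, ref_D2.values.shape[1], nfac))
    rho_all = np.empty((n_repeats, nfac))
    r_age_all = np.empty(n_repeats)

    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        order = rng.permutation(n)
        bounds = np.cumsum([0] + _fold_sizes(n, k))
        F1_hold = np.empty((n, nfac))
        F2_hold = np.empty((n, nfac))
        for f in range(k):
            test_idx = order[bounds[f]:bounds[f + 1]]
            train_idx = np.setdiff1d(order, test_idx)
            trained = fit_two_view(
                _subset(D1, train_idx), _subset(D2, train_idx),
                _subset_conf(confounds, train_idx), n_comp_pair,
                age=age[train_idx], deconfound_age=deconfound_age,
            )
            perm, signs = _align_to_reference(trained, reference)
            F1t, F2t = holdout_project(
                trained, _subset(D1, test_idx), _subset(D2, test_idx),
                _subset_conf(confounds, test_idx), age_test=age[test_idx],
            )
            F1_hold[test_idx] = F1t[:, perm] * signs
            F2_hold[test_idx] = F2t[:, perm] * signs
        F1_all[rep] = F1_hold
        F2_all[rep] = F2_hold
        with np.errstate(invalid="ignore"):
            for j in range(nfac):
                rho_all[rep, j] = np.corrcoef(F1_hold[:, j], F2_hold[:, j])[0, 1]
        L1_all[rep] = compute_loadings(ref_D1, F1_hold)
        L2_all[rep] = compute_loadings(ref_D2, F2_hold)
        r_age_all[rep] = age_correlation(F1_hold[:, 0], F2_hold[:, 0], age).r_age

    def med_se(arr):
        return np.median(arr, axis=0), arr.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros_like(arr[0])

    F1_med, F1_se = med_se(F1_all)
    F2_med, F2_se = med_se(F2_all)
    L1_med, L1_se = med_se(L1_all)
    L2_med, L2_se = med_se(L2_all)
    rho_med, rho_se = med_se(rho_all)
    return CrossValResult(
        holdout_F1=F1_med, holdout_F2=F2_med, holdout_F1_se=F1_se, holdout_F2_se=F2_se,
        holdout_L1=L1_med, holdout_L2=L2_med, holdout_L1_se=L1_se, holdout_L2_se=L2_se,
        rho_median=rho_med, rho_se=rho_se,
        r_age_median=float(np.median(r_age_all)),
        r_age_se=float(r_age_all.std(ddof=1)) if n_repeats > 1 else 0.0,
        rho1_repeats=rho_all[:, 0], r_age_repeats=r_age_all,
        n_repeats=n_repeats, k=k, seed=seed,
    )


def grid_plan(p_min: int = 2, p_max: int = 100, n_throws: int = 15000) -> dict:
    """Bookkeeping for the full hyperparameter sweep (counting only).

    Returns the number of grid cells (all (p_brain, p_behavior) pairs in
    [p_min, p_max]^2) and the total number of model evaluations when each
    cell is cross-validated with ``n_throws`` repeated k-fold throws.
    """
    if p_max < p_min:
        raise ValueError("empty grid range")
    side = p_max - p_min + 1
    n_cells = side * side
    return {"n_cells": n_cells, "n_model_evaluations": n_cells * n_throws}


def grid_search(
    D1: SubjectFeatureTable,
    D2: SubjectFeatureTable,
    age: np.ndarray,
    confounds: ConfoundTable | pd.DataFrame | None = None,
    p_range: tuple[int, int] = (2, 10),
    k: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    step: int = 1,
    deconfound_age: bool = False,
    n_jobs: int = 1,
) -> GridSearchResult:
    """Grid search over PCA component pairs, scored by cross-validated r_age.

    Every evaluated cell is a pure function of (pair, seed): the per-cell
    CV seed derives from ``SeedSequence([seed, p1, p2])``, so coarse grids
    (``step > 1``) and parallel execution reproduce the same numbers as the
    dense sequential sweep for the cells they share.  Ties on the maximal
    median r_age break to the smallest brain then behavior component count.
    """
    lo, hi = p_range
    if hi < lo:
        raise ValueError("empty grid range")
    ps = list(range(lo, hi + 1, step))
    pairs = [(p1, p2) for p1 in ps for p2 in ps]

    def eval_cell(pair):
        cell_seed = np.random.SeedSequence([seed, pair[0], pair[1]]).generate_state(1)[0] % (2**31)
        cv = repeated_kfold_cca(
            D1, D2, age, confounds=confounds, k=k, n_repeats=n_repeats,
            n_comp_pair=(pair[1], pair[0]), seed=int(cell_seed),
            deconfound_age=deconfound_age,
        )
        return pair[0], pair[1], cv.r_age_median, cv.r_age_se

    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(delayed(eval_cell)(p) for p in pairs)
    else:
        rows = [eval_cell(p) for p in pairs]
    grid = pd.DataFrame(rows, columns=["p_brain", "p_behavior", "r_age_median", "r_age_se"])
    best_idx = grid.sort_values(
        ["r_age_median", "p_brain", "p_behavior"], ascending=[False, True, True]
    ).index[0]
    best = (int(grid.loc[best_idx, "p_brain"]), int(grid.loc[best_idx, "p_behavior"]))
    side = hi - lo + 1
    return GridSearchResult(
        grid=grid, best_pair=best, n_cells=len(pairs),
        n_models_total=side * side * n_repeats,
    )
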