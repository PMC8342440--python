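"""Representational similarity analysis on canonical loadings.

Each variable (network node or behavior measure) is described by its
vector of loadings across all canonical factors; the dissimilarity between
two variables is ``1 - |corr|`` of those vectors, so variables that load
the same way (or exactly oppositely) across factors are maximally similar.
Stacking network and behavior loadings yields one square dissimilarity
matrix whose network-network, behavior-behavior and behavior-to-network
(btn) blocks can be module-averaged, differenced between model variants to
isolate age-dependent structure, and thresholded into chord-plot data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RsaMatrix",
    "ModuleLoadingSummary",
    "loading_dissimilarity",
    "module_average",
    "rsa_difference",
    "chord_data",
    "module_loading_summary",
]


@dataclass
class RsaMatrix:
    values: pd.DataFrame          # symmetric, zero diagonal, entries in [0, 1]
    row_domains: pd.Series        # "network" or "behavior" per row

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def block(self, rows: str, cols: str) -> pd.DataFrame:
        ri = self.row_domains[self.row_domains == rows].index
        ci = self.row_domains[self.row_domains == cols].index
        return self.values.loc[ri, ci]


@dataclass
class ModuleLoadingSummary:
    table: pd.DataFrame  # index module; positive_mean, negative_mean, pos/neg se, flags


def loading_dissimilarity(
    L_stacked: pd.DataFrame | np.ndarray,
    row_domains: pd.Series | None = None,
) -> RsaMatrix:
    """Pairwise loading dissimilarity ``S[u, v] = 1 - |corr(L[u,:], L[v,:])|``.

    Rows are variables, columns canonical factors (>= 2 needed for a
    correlation across factors).  Constant loading rows make the Pearson
    correlation undefined and raise with the offending variable named.

    Whole-row sign flips (a variable reversing its meaning) are absorbed
    exactly by the absolute value.  Factor-column signs, by contrast, do
    change Pearson row correlations; the pipeline therefore fixes factor
    orientations deterministically upstream (CCA sign convention and
    cross-validation alignment) before loadings reach the RSA.
    """
    if isinstance(L_stacked, np.ndarray):
        L = pd.DataFrame(L_stacked, index=[f"var-{i}" for i in range(L_stacked.shape[0])])
    else:
        L = L_stacked
    if L.shape[1] < 2:
        raise ValueError("need at least 2 factors")
    arr = L.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        bad = list(L.index[sd == 0])
        raise ValueError(f"constant loading rows: {bad}")
    C = np.corrcoef(arr)
    S = 1.0 - np.abs(C)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 0.0)
    if row_domains is None:
        row_domains = pd.Series(["unknown"] * len(L), index=L.index)
    return RsaMatrix(pd.DataFrame(S, index=L.index, columns=L.index), row_domains.loc[L.index])


def module_average(
    S: RsaMatrix, module_map: pd.Series, module_order: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean (and SD) of S over each module pair, excluding diagonal cells of S.

    ``module_map`` assigns every row of S to a module (network modules and
    behavior domains combined).  Returns (mean matrix, SD matrix) in
    ``module_order`` (default: order of first appearance).
    """
    missing = set(S.values.index) - set(module_map.index)
    if missing:
        raise ValueError(f"module map does not cover rows: {sorted(missing)[:5]} ...")
    labels = module_map.loc[S.values.index]
    if module_order is None:
        module_order = list(dict.fromkeys(labels))
    for m in module_order:
        if (labels == m).sum() == 0:
            raise ValueError(f"empty module: {m}")
    vals = S.values.to_numpy()
    n = len(labels)
    eye = np.eye(n, dtype=bool)
    mean = pd.DataFrame(index=module_order, columns=module_order, dtype=float)
    sd = mean.copy()
    idx = {m: np.flatnonzero((labels == m).to_numpy()) for m in module_order}
    for a in module_order:
        for b in module_order:
            block = vals[np.ix_(idx[a], idx[b])]
            mask = ~eye[np.ix_(idx[a], idx[b])]
            cells = block[mask]
            if cells.size == 0:
                # singleton module self-pair: only the diagonal cell exists,
                # whose dissimilarity is 0 by definition
                mean.loc[a, b] = 0.0
                sd.loc[a, b] = 0.0
            else:
                mean.loc[a, b] = cells.mean()
                sd.loc[a, b] = cells.std(ddof=1) if cells.size > 1 else 0.0
    return mean, sd


def rsa_difference(S1_modules: pd.DataFrame, S2_modules: pd.DataFrame) -> pd.DataFrame:
    """Elementwise module-matrix difference S_d = S1 - S2.

    S1 is the full model's module-averaged dissimilarity and S2 the
    age-deconfounded model's; where age drives a brain-behavior coupling,
    removing it decouples the loadings, so the corresponding S_d cells move
    away from zero.
    """
    if list(S1_modules.index) != list(S2_modules.index) or list(S1_modules.columns) != list(S2_modules.columns):
        raise ValueError("module label mismatch between S1 and S2")
    return S1_modules - S2_modules


def chord_data(btn_block: pd.DataFrame, percentile: float = 75.0) -> dict:
    """Chord-plot data from a brain-to-behavior dissimilarity block.

    The block is converted back to similarity ``r = 1 - S``, min-max
    normalized to [0, 1]; entries strictly below-or-at the given sample
    percentile (linear interpolation) are eliminated, and survivors are
    transformed as ``(r * 1000)^2``.  Returns the weighted bipartite edge
    list and per-segment totals (chord wedge sizes).
    """
    r = 1.0 - btn_block.to_numpy(dtype=float)
    if r.size == 0:
        raise ValueError("empty block")
    if r.max() == r.min():
        raise ValueError("constant block: percentile cut undefined")
    rn = (r - r.min()) / (r.max() - r.min())
    cut = np.percentile(rn, percentile)
    keep = rn > cut
    w = np.where(keep, (rn * 1000.0) ** 2, 0.0)
    edges = [
        (btn_block.index[i], btn_block.columns[j], float(w[i, j]))
        for i, j in zip(*np.nonzero(keep))
    ]
    wedge_rows = {str(m): float(w[i, :].sum()) for i, m in enumerate(btn_block.index)}
    wedge_cols = {str(d): float(w[:, j].sum()) for j, d in enumerate(btn_block.columns)}
    return {
        "edges": edges,
        "row_totals": wedge_rows,
        "col_totals": wedge_cols,
        "percentile_cut": float(cut),
        "n_edges": len(edges),
    }


def module_loading_summary(
    L_ca1: pd.Series, module_map: pd.Series, ses: pd.Series | None = None,
    scale: str = "mean",
) -> ModuleLoadingSummary:
    """Positive/negative mean first-axis loadings per module, for word clouds.

    Per module, positive loadings average into a positive mean and negative
    loadings into a negative mean; each side carries the mean of the
    contributing variables' cross-validation SEs.  ``scale`` selects the
    word-cloud scale value: the mean magnitude (default) or the summed
    magnitude per side.
    """
    if scale not in ("mean", "sum"):
        raise ValueError("scale must be 'mean' or 'sum'")
    missing = set(L_ca1.index) - set(module_map.index)
    if missing:
        raise ValueError(f"module map does not cover variables: {sorted(missing)[:5]}")
    rows = []
    for mod in dict.fromkeys(module_map.loc[L_ca1.index]):
        sel = L_ca1.index[(module_map.loc[L_ca1.index] == mod)]
        vals = L_ca1.loc[sel]
        pos, neg = vals[vals > 0], vals[vals < 0]
        se_pos = se_neg = np.nan
        if ses is not None:
            se_pos = float(ses.loc[pos.index].mean()) if len(pos) else np.nan
            se_neg = float(ses.loc[neg.index].mean()) if len(neg) else np.nan
        agg = (lambda s: float(s.mean())) if scale == "mean" else (lambda s: float(s.sum()))
        rows.append({
            "module": mod,
            "positive_mean": float(pos.mean()) if len(pos) else 0.0,
            "negative_mean": float(neg.mean()) if len(neg) else 0.0,
            "positive_empty": len(pos) == 0,
            "negative_empty": len(neg) == 0,
            "positive_se": se_pos,
            "negative_se": se_neg,
            "positive_scale": abs(agg(pos)) if len(pos) else 0.0,
            "negative_scale": abs(agg(neg)) if len(neg) else 0.0,
        })
    return ModuleLoadingSummary(pd.DataFrame(rows).set_index("module"))
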