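"""Structural-network features from streamline counts.

Edges are weighted by connection density: the number of streamlines
terminating in two parcels, normalized by the parcels' combined voxel
count, ``C_d = 2 s_ij / (n_i + n_j)``.  A consensus threshold removes
edges that are not present in a strict majority of subjects, node degree
counts the surviving nonzero edges, and lifespan trends of graph summaries
are fit as quadratics on decade-bin means.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .synthdata import ConnectomeStack

__all__ = [
    "DensityNetworkSet",
    "TrendFit",
    "connection_density",
    "build_density_networks",
    "consensus_threshold",
    "node_degree",
    "degree_table",
    "graph_summaries",
    "quadratic_trend",
]


@dataclass
class DensityNetworkSet:
    densities: np.ndarray  # (n_subjects, n_nodes, n_nodes) connection densities
    edge_mask: np.ndarray | None  # symmetric bool, None before thresholding
    node_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.densities.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.densities.shape[1]


@dataclass
class TrendFit:
    quadratic_term: float
    coefficients: np.ndarray  # (quadratic, linear, intercept)
    r_squared: float
    aicc: float
    n_points: int
    constant_input: bool = False


def connection_density(s_ij, n_i, n_j):
    """Streamline density of one connection, ``2 s_ij / (n_i + n_j)``.

    Accepts scalars or arrays; voxel counts must be positive.
    """
    s_ij = np.asarray(s_ij, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    if np.any(n_i <= 0) or np.any(n_j <= 0):
        raise ValueError("voxel counts must be positive")
    if np.any(s_ij < 0):
        raise ValueError("streamline counts must be nonnegative")
    out = 2.0 * s_ij / (n_i + n_j)
    return out.item() if out.ndim == 0 else out


def build_density_networks(stack: ConnectomeStack) -> DensityNetworkSet:
    """Elementwise connection density for every subject; symmetry preserved."""
    v = stack.voxel_counts.astype(float)
    denom = v[:, None] + v[None, :]
    dens = 2.0 * stack.counts / denom[None, :, :]
    dens[:, np.arange(stack.n_nodes), np.arange(stack.n_nodes)] = 0.0
    return DensityNetworkSet(densities=dens, edge_mask=None, node_ids=list(stack.node_ids))


def consensus_threshold(nets: DensityNetworkSet, min_prop: float = 0.5) -> DensityNetworkSet:
    """Keep an edge iff it is nonzero in a strict majority (> min_prop) of subjects."""
    if nets.n_subjects < 1:
        raise ValueError("need at least one subject")
    present = (nets.densities > 0).sum(axis=0)
    mask = present > min_prop * nets.n_subjects
    np.fill_diagonal(mask, False)
    dens = np.where(mask[None, :, :], nets.densities, 0.0)
    return DensityNetworkSet(densities=dens, edge_mask=mask, node_ids=list(nets.node_ids))


def node_degree(nets: DensityNetworkSet) -> np.ndarray:
    """Binary degree per subject per node: count of nonzero surviving edges."""
    return (nets.densities > 0).sum(axis=2)


def degree_table(nets: DensityNetworkSet, subject_ids: list[str]) -> pd.DataFrame:
    deg = node_degree(nets)
    return pd.DataFrame(deg, index=subject_ids, columns=nets.node_ids)


def graph_summaries(net: np.ndarray) -> dict:
    """Highest node degree, edge density and binary global efficiency of one network.

    Efficiency is the mean over ordered node pairs of the inverse shortest
    path length on the binarized graph; disconnected pairs contribute 0.
    """
    net = np.asarray(net)
    n = net.shape[0]
    if n < 2:
        raise ValueError("graph summaries undefined for fewer than 2 nodes")
    adj = (net > 0) & ~np.eye(n, dtype=bool)
    deg = adj.sum(axis=1)
    n_edges = int(adj.sum()) // 2
    g = nx.from_numpy_array(adj.astype(int))
    return {
        "highest_degree": int(deg.max()),
        "density": n_edges / (n * (n - 1) / 2),
        "efficiency": nx.global_efficiency(g),
    }


def quadratic_trend(values: np.ndarray, ages: np.ndarray, n_bins: int = 7,
                    age_start: float = 18.0, bin_width: float = 10.0) -> TrendFit:
    """Quadratic lifespan trend on decade-bin means.

    Subjects are binned by decades starting at ``age_start``; the per-bin
    means of ``values`` are fit with an OLS quadratic against bin centers.
    AICc uses the Gaussian log-likelihood form ``n ln(RSS/n) + 2k +
    2k(k+1)/(n-k-1)`` with k = 3 parameters and n = number of bins.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    k = 3
    if n_bins <= k + 1:
        raise ValueError("AICc undefined: need n_bins > 4")
    edges = age_start + bin_width * np.arange(n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    idx = np.clip(np.digitize(ages, edges[1:-1]), 0, n_bins - 1)
    means = np.array([values[idx == b].mean() if (idx == b).any() else np.nan
                      for b in range(n_bins)])
    ok = np.isfinite(means)
    if ok.sum() < k + 1:
        raise ValueError("too few populated bins for a quadratic fit")
    x, y = centers[ok], means[ok]
    nb = ok.sum()
    if np.allclose(y, y[0]):
        return TrendFit(0.0, np.array([0.0, 0.0, y[0]]), 0.0, -np.inf, int(nb), True)
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    with np.errstate(divide="ignore"):
        aicc = nb * np.log(rss / nb) + 2 * k + 2 * k * (k + 1) / (nb - k - 1)
    return TrendFit(float(coeffs[0]), coeffs, float(r2), float(aicc), int(nb))
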