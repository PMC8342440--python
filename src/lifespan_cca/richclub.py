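"""Rich-club partition of the group-average network and its relation to
first-axis canonical loadings.

The group network is the elementwise mean of the per-subject density
matrices with a simple-majority consensus threshold.  The rich club is the
top fraction of nodes by min-max-normalized binary degree (default
fraction 54/376, reproducing a 54-core / 322-periphery split on a 376-node
network); the participation coefficient is, as used here, the ratio of a
node's within-group to between-group connection counts (a normalized
within/total variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .netfeatures import DensityNetworkSet

__all__ = [
    "RichClubPartition",
    "average_network",
    "rich_club_partition",
    "participation_coefficient",
    "loading_degree_association",
]

DEFAULT_CORE_FRACTION = 54 / 376


@dataclass
class RichClubPartition:
    mean_network: np.ndarray
    degree: np.ndarray
    norm_degree: np.ndarray
    core_nodes: np.ndarray       # indices, sorted
    periphery_nodes: np.ndarray
    fraction: float

    @property
    def is_core(self) -> np.ndarray:
        m = np.zeros(len(self.degree), dtype=bool)
        m[self.core_nodes] = True
        return m


def average_network(nets: DensityNetworkSet, min_prop: float = 0.5) -> np.ndarray:
    """Elementwise mean density matrix; edges not present in a strict
    majority of subjects are zeroed after averaging."""
    if nets.n_subjects < 1:
        raise ValueError("need at least one subject")
    mean = nets.densities.mean(axis=0)
    present = (nets.densities > 0).sum(axis=0)
    mean[present <= min_prop * nets.n_subjects] = 0.0
    np.fill_diagonal(mean, 0.0)
    return mean


def rich_club_partition(mean_net: np.ndarray, fraction: float = DEFAULT_CORE_FRACTION) -> RichClubPartition:
    """Split nodes into a high-degree core and a periphery.

    Degree is the binary degree on the mean network's surviving edges,
    min-max normalized; the core holds the ``round(fraction * n)`` nodes of
    highest normalized degree, with ties broken by node index.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    mean_net = np.asarray(mean_net)
    n = mean_net.shape[0]
    deg = ((mean_net > 0) & ~np.eye(n, dtype=bool)).sum(axis=1).astype(float)
    if deg.max() == deg.min():
        raise ValueError("constant node degree: rich-club partition undefined")
    norm = (deg - deg.min()) / (deg.max() - deg.min())
    n_core = int(round(fraction * n))
    # sort by (-degree, node index): deterministic tie-break by index
    order = np.lexsort((np.arange(n), -norm))
    core = np.sort(order[:n_core])
    periph = np.sort(order[n_core:])
    return RichClubPartition(
        mean_network=mean_net, degree=deg, norm_degree=norm,
        core_nodes=core, periphery_nodes=periph, fraction=fraction,
    )


def participation_coefficient(
    mean_net: np.ndarray, partition: RichClubPartition, normalized: bool = False
) -> np.ndarray:
    """Per-node within/between connection-count ratio on the mean network.

    Nodes with no between-group connections get NaN (undefined ratio, not
    infinity).  With ``normalized=True`` the standard bounded alternative
    within/(within+between) is returned instead.
    """
    mean_net = np.asarray(mean_net)
    n = mean_net.shape[0]
    adj = (mean_net > 0) & ~np.eye(n, dtype=bool)
    is_core = partition.is_core
    same = is_core[:, None] == is_core[None, :]
    within = (adj & same).sum(axis=1).astype(float)
    between = (adj & ~same).sum(axis=1).astype(float)
    if normalized:
        tot = within + between
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, within / tot, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(between > 0, within / between, np.nan)


def _boot_p_greater(rng, stat_obs, null_draw, n_boot):
    null = np.array([null_draw(rng) for _ in range(n_boot)])
    return float((null >= stat_obs).mean())


def loading_degree_association(
    loadings_ca1: np.ndarray,
    partition: RichClubPartition,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Relate first-axis node loadings to node degree and the rich club.

    Returns the mean CA1 loading in core and periphery (with a resampling p
    for their difference), and Spearman rank correlations of loading versus
    degree over all nodes, core only and periphery only, each with a
    pairing-breaking resampling p and a bootstrap SE.  Rank correlations
    are insensitive to the min-max degree normalization.
    """
    x = np.asarray(loadings_ca1, float).ravel()
    deg = partition.degree
    if len(x) != len(deg):
        raise ValueError("loadings and degree are not aligned")
    is_core = partition.is_core
    if is_core.sum() < 3 or (~is_core).sum() < 3:
        raise ValueError("core or periphery smaller than 3 nodes")
    rng = np.random.default_rng(seed)
    out = {
        "core_mean_loading": float(x[is_core].mean()),
        "periphery_mean_loading": float(x[~is_core].mean()),
    }
    obs_diff = out["core_mean_loading"] - out["periphery_mean_loading"]

    def diff_null(r):
        perm = r.permutation(len(x))
        xs = x[perm]
        return xs[is_core].mean() - xs[~is_core].mean()

    null = np.array([diff_null(rng) for _ in range(n_boot)])
    out["mean_difference"] = float(obs_diff)
    out["mean_difference_p"] = float((np.abs(null) >= abs(obs_diff)).mean())

    for name, sel in (("all", np.ones_like(is_core)), ("core", is_core), ("periphery", ~is_core)):
        xs, ds = x[sel], deg[sel]
        r_obs = stats.spearmanr(xs, ds).statistic
        null_r = np.empty(n_boot)
        boot_r = np.empty(n_boot)
        m = len(xs)
        with warnings.catch_warnings():
            # degenerate resamples (all-tied ranks) yield NaN and are ignored
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            for i in range(n_boot):
                null_r[i] = stats.spearmanr(xs[rng.integers(0, m, m)], ds).statistic
                idx = rng.integers(0, m, m)
                boot_r[i] = stats.spearmanr(xs[idx], ds[idx]).statistic
        out[f"spearman_{name}"] = float(r_obs)
        out[f"spearman_{name}_p"] = float((null_r >= r_obs).mean())
        out[f"spearman_{name}_se"] = float(np.nanstd(boot_r, ddof=1))
    return out
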