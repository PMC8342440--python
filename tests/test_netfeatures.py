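import numpy as np
import pytest

from lifespan_cca import netfeatures as nf
from lifespan_cca.netfeatures import DensityNetworkSet
from lifespan_cca.synthdata import ConnectomeStack


def _stack_from_matrices(mats, voxels):
    counts = np.stack(mats).astype(np.int64)
    return ConnectomeStack(counts=counts, voxel_counts=np.asarray(voxels),
                           node_ids=[f"n{i}" for i in range(counts.shape[1])])


def _nets_from_dense(mats):
    dens = np.stack(mats).astype(float)
    return DensityNetworkSet(densities=dens, edge_mask=None,
                             node_ids=[f"n{i}" for i in range(dens.shape[1])])


@pytest.mark.parametrize(
    "s,ni,nj,expected",
    [(10, 100, 100, 0.1), (0, 50, 80, 0.0), (7, 50, 90, 0.1)],
)
def test_connection_density_values(s, ni, nj, expected):
    assert nf.connection_density(s, ni, nj) == pytest.approx(expected, abs=1e-12)


def test_connection_density_rejects_bad_inputs():
    with pytest.raises(ValueError):
        nf.connection_density(1, 0, 10)
    with pytest.raises(ValueError):
        nf.connection_density(-1, 10, 10)


def test_build_density_networks_small_case():
    m = np.zeros((3, 3), dtype=int)
    m[0, 1] = m[1, 0] = 4
    m[1, 2] = m[2, 1] = 2
    stack = _stack_from_matrices([m], [10, 10, 10])
    nets = nf.build_density_networks(stack)
    d = nets.densities[0]
    assert d[0, 1] == pytest.approx(0.4)
    assert d[0, 2] == pytest.approx(0.0)
    assert d[1, 2] == pytest.approx(0.2)
    assert np.allclose(d, d.T)


def test_build_density_networks_zero_counts():
    stack = _stack_from_matrices([np.zeros((4, 4), dtype=int)], [5, 5, 5, 5])
    assert nf.build_density_networks(stack).densities.sum() == 0.0


def test_unique_edge_count_matches_upper_triangle():
    n = 376
    assert n * (n - 1) // 2 == 70500


@pytest.mark.parametrize("n_present,kept", [(2, False), (10, True), (5, False)])
def test_consensus_threshold_strict_majority(n_present, kept):
    """Edge nonzero in exactly half of 10 subjects is removed (strict majority)."""
    mats = []
    for i in range(10):
        m = np.zeros((3, 3))
        if i < n_present:
            m[0, 1] = m[1, 0] = 0.5
        mats.append(m)
    nets = nf.consensus_threshold(_nets_from_dense(mats))
    assert bool(nets.edge_mask[0, 1]) is kept
    assert (nets.densities[:, 0, 1] > 0).any() is np.bool_(kept)
    # brute-force recount agrees
    assert kept == (sum(m[0, 1] > 0 for m in mats) > 5)


def test_threshold_monotone_in_min_prop(rng):
    mats = [np.triu((rng.random((6, 6)) < 0.5).astype(float), 1) for _ in range(9)]
    mats = [m + m.T for m in mats]
    nets = _nets_from_dense(mats)
    prev = None
    for prop in (0.2, 0.5, 0.8):
        mask = nf.consensus_threshold(nets, min_prop=prop).edge_mask
        if prev is not None:
            assert not (mask & ~prev).any()  # raising min_prop never adds edges
        prev = mask


def test_node_degree_examples():
    full = np.ones((5, 5)) - np.eye(5)
    path = np.zeros((3, 3))
    path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
    nets = nf.consensus_threshold(_nets_from_dense([full]))
    assert list(nf.node_degree(nets)[0]) == [4] * 5
    nets = nf.consensus_threshold(_nets_from_dense([path]))
    assert list(nf.node_degree(nets)[0]) == [1, 2, 1]
    empty = nf.consensus_threshold(_nets_from_dense([np.zeros((4, 4))]))
    assert nf.node_degree(empty).sum() == 0


def test_degree_sum_equals_twice_edges(rng):
    mats = [np.triu((rng.random((8, 8)) < 0.6).astype(float), 1) for _ in range(5)]
    mats = [m + m.T for m in mats]
    nets = nf.consensus_threshold(_nets_from_dense(mats))
    deg = nf.node_degree(nets)
    for i in range(5):
        n_edges = (nets.densities[i] > 0).sum() // 2
        assert deg[i].sum() == 2 * n_edges


def test_graph_summaries_closed_forms():
    k4 = np.ones((4, 4)) - np.eye(4)
    s = nf.graph_summaries(k4)
    assert (s["highest_degree"], s["density"], s["efficiency"]) == (3, 1.0, 1.0)
    s = nf.graph_summaries(np.zeros((4, 4)))
    assert (s["highest_degree"], s["density"], s["efficiency"]) == (0, 0.0, 0.0)
    path4 = np.zeros((4, 4))
    for i in range(3):
        path4[i, i + 1] = path4[i + 1, i] = 1.0
    assert nf.graph_summaries(path4)["efficiency"] == pytest.approx(13 / 18)
    with pytest.raises(ValueError):
        nf.graph_summaries(np.zeros((1, 1)))


def _brute_force_summaries(adj):
    """Floyd-Warshall reference for density/efficiency/degree on tiny graphs."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
    inv = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    inv[finite] = 1.0 / dist[finite]
    return {
        "highest_degree": int((adj > 0).sum(1).max()),
        "density": (adj > 0).sum() / 2 / (n * (n - 1) / 2),
        "efficiency": inv[off].mean(),
    }


@pytest.mark.parametrize("seed", range(6))
def test_graph_summaries_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    adj = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
    adj = adj + adj.T
    got = nf.graph_summaries(adj)
    want = _brute_force_summaries(adj)
    for key in want:
        assert got[key] == pytest.approx(want[key], abs=1e-12)


def test_quadratic_trend_exact_on_bin_centers():
    centers = 23.0 + 10.0 * np.arange(7)
    ages = np.repeat(centers, 10)
    vals = -0.005 * ages**2 + 0.4 * ages + 2.0
    fit = nf.quadratic_trend(vals, ages)
    assert fit.quadratic_term == pytest.approx(-0.005, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert fit.n_points == 7
    assert np.isfinite(fit.aicc)


def test_quadratic_trend_constant_flagged():
    ages = np.linspace(18, 88, 70)
    fit = nf.quadratic_trend(np.ones(70), ages)
    assert fit.constant_input
    assert fit.quadratic_term == 0.0


def test_quadratic_trend_inverted_u_negative():
    rng = np.random.default_rng(0)
    ages = rng.uniform(18, 88, 400)
    vals = -((ages - 40.0) ** 2) + rng.normal(0, 30, 400)
    assert nf.quadratic_trend(vals, ages).quadratic_term < 0


def test_quadratic_trend_too_few_bins():
    with pytest.raises(ValueError):
        nf.quadratic_trend(np.arange(40.0), np.linspace(18, 58, 40), n_bins=4)
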