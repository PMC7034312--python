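"""Graph construction and small-world metrics against independent oracles."""

import numpy as np
import networkx as nx
import pytest

from nirsnet import (
    BinaryGraph,
    ConnectivityMatrix,
    binarize,
    clustering_coefficient,
    connectivity,
    global_efficiency,
    graph_metrics,
    path_length,
    random_reference,
    sigma,
    threshold_sweep,
)
from nirsnet.preprocess import HemoTimeSeries


def _graph(adj):
    return BinaryGraph(adjacency=np.asarray(adj), mode="sparsity", threshold=0.5)


def _hemo(x):
    return HemoTimeSeries(
        hbo=x, hbr=-x, fs=10.0,
        channels=[f"CH{i:02d}" for i in range(1, x.shape[0] + 1)],
    )


# ------------------------------------------------------------ connectivity

def test_connectivity_of_duplicated_and_negated_channels():
    rng = np.random.default_rng(0)
    base = rng.standard_normal(500)
    x = np.vstack([base, base, -base])
    c = connectivity(_hemo(x))
    assert c.r[0, 1] == pytest.approx(1.0)
    assert c.r[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(c.r), 1.0)


def test_independent_channels_have_near_zero_correlation():
    rng = np.random.default_rng(42)
    x = rng.standard_normal((2, 10_000))
    c = connectivity(_hemo(x))
    assert abs(c.r[0, 1]) < 0.05


def test_constant_channel_rejected_by_name():
    x = np.vstack([np.ones(100), np.arange(100.0)])
    with pytest.raises(ValueError, match="CH01"):
        connectivity(_hemo(x))


# ------------------------------------------------------------ binarize

def _corr_matrix(upper):
    n = int((1 + np.sqrt(1 + 8 * len(upper))) / 2)
    r = np.eye(n)
    r[np.triu_indices(n, 1)] = upper
    r = r + r.T - np.diag(np.diag(r))
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, channels=tuple(f"C{i}" for i in range(n)))


def test_sparsity_keeps_strongest_positive_edges():
    c = _corr_matrix([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
    g = binarize(c, "sparsity", 0.5)
    assert g.n_edges == 3
    kept = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if g.adjacency[i, j]}
    strongest = {(0, 1), (0, 2), (0, 3)}  # r = .9, .8, .7 in row-major upper order
    assert kept == strongest
    # sparsity 1 on an all-positive matrix yields the complete graph
    assert binarize(c, "sparsity", 1.0).n_edges == 6


def test_correlation_mode_threshold_and_negative_edges():
    c = _corr_matrix([0.9, -0.95, 0.7, 0.4, 0.3, 0.2])
    g = binarize(c, "correlation", 0.65)
    assert g.n_edges == 2  # 0.9 and 0.7; the -0.95 never connects
    assert binarize(c, "correlation", 0.95).n_edges == 0
    # negative coefficients are also skipped in sparsity mode
    g2 = binarize(c, "sparsity", 1.0)
    assert g2.n_edges == 5
    with pytest.raises(ValueError):
        binarize(c, "sparsity", 1.5)
    with pytest.raises(ValueError):
        binarize(c, "correlation", 1.0)


# ------------------------------------------------------------ metric kernels

K4 = np.ones((4, 4)) - np.eye(4)
STAR = np.zeros((4, 4)); STAR[0, 1:] = 1; STAR += STAR.T
PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.mark.parametrize(
    "adj, cp, lp, eg",
    [
        (K4, 1.0, 1.0, 1.0),
        (STAR, 0.0, 1.5, 0.75),
        (PATH3, 0.0, 4 / 3, 5 / 6),
        (np.zeros((3, 3)), 0.0, np.nan, 0.0),
    ],
)
def test_metrics_on_canonical_graphs(adj, cp, lp, eg):
    g = _graph(adj)
    assert clustering_coefficient(g) == pytest.approx(cp)
    got_lp, n_disc = path_length(g)
    if np.isnan(lp):
        assert np.isnan(got_lp) and n_disc == 6
    else:
        assert got_lp == pytest.approx(lp)
    assert global_efficiency(g) == pytest.approx(eg)


def _brute_force_metrics(adj):
    """Independent oracle: explicit triangle enumeration + Floyd-Warshall."""
    n = len(adj)
    cs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(
            adj[a][b] for ai, a in enumerate(nb) for b in nb[ai + 1:]
        )
        cs.append(2.0 * t / (k * (k - 1)))
    d = [[0 if i == j else (1 if adj[i][j] else np.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    finite, inv = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i][j]):
                finite.append(d[i][j])
                inv.append(1.0 / d[i][j])
    lp = float(np.mean(finite)) if finite else float("nan")
    eg = float(np.sum(inv) / (n * (n - 1)))
    return float(np.mean(cs)), lp, eg


def test_metric_kernels_match_oracles_on_random_graphs():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = int(rng.integers(4, 14))
        p = rng.uniform(0.15, 0.8)
        adj = (rng.random((n, n)) < p).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        g = _graph(adj)
        cp_o, lp_o, eg_o = _brute_force_metrics(adj)
        assert clustering_coefficient(g) == pytest.approx(cp_o, abs=1e-12)
        lp, _ = path_length(g)
        if np.isnan(lp_o):
            assert np.isnan(lp)
        else:
            assert lp == pytest.approx(lp_o, abs=1e-12)
        assert global_efficiency(g) == pytest.approx(eg_o, abs=1e-12)


# ------------------------------------------------------------ null model

def test_null_ensemble_preserves_degrees_and_is_deterministic():
    rng = np.random.default_rng(3)
    adj = (rng.random((10, 10)) < 0.4).astype(int)
    adj = np.triu(adj, 1); adj = adj + adj.T
    g = _graph(adj)
    got1 = random_reference(g, n_null=5, seed=9)
    got2 = random_reference(g, n_null=5, seed=9)
    assert got1 == got2
    # degree preservation is an invariant of the swap move itself
    base = nx.from_numpy_array(g.adjacency)
    swapped = base.copy()
    nx.double_edge_swap(swapped, nswap=30, max_tries=3000, seed=1)
    assert sorted(dict(base.degree).values()) == sorted(dict(swapped.degree).values())
    assert not any(swapped.has_edge(v, v) for v in swapped)


def test_lattice_clusters_more_than_its_random_reference():
    g = _graph(nx.to_numpy_array(nx.watts_strogatz_graph(20, 4, 0.0)))
    c_rand, _ = random_reference(g, n_null=20, seed=0)
    assert clustering_coefficient(g) > c_rand


def test_star_degree_sequence_falls_back_with_warning():
    with pytest.warns(UserWarning, match="no degree-preserving swap"):
        c_rand, l_rand = random_reference(_graph(STAR), n_null=5, seed=0)
    assert c_rand == clustering_coefficient(_graph(STAR))


def test_sigma_of_canonical_graphs():
    g = _graph(K4)
    lp, _ = path_length(g)
    assert sigma(g, (clustering_coefficient(g), lp)) == pytest.approx(1.0)
    ws = _graph(nx.to_numpy_array(nx.watts_strogatz_graph(20, 4, 0.1, seed=4)))
    m = graph_metrics(ws, n_null=50, seed=5)
    assert m.sigma > 1.0
    dense = nx.gnp_random_graph(20, 0.8, seed=8)
    m2 = graph_metrics(_graph(nx.to_numpy_array(dense)), n_null=50, seed=5)
    assert m2.sigma == pytest.approx(1.0, abs=0.2)


# ------------------------------------------------------------ sweep

def test_threshold_sweep_consistency_and_monotonicity():
    rng = np.random.default_rng(21)
    x = rng.standard_normal((8, 600))
    x += 0.5 * rng.standard_normal((1, 600))  # common signal => positive r
    c = connectivity(_hemo(x))
    grid = np.round(np.arange(0.1, 0.9 + 1e-9, 0.1), 10)
    sweep = threshold_sweep(c, grid=grid, n_null=10, seed=2)
    edges = [m.n_edges for m in sweep]
    egs = [m.eg for m in sweep]
    assert edges == sorted(edges)
    assert all(b >= a - 1e-12 for a, b in zip(egs, egs[1:]))
    # one-point sweep equals a standalone binarize + metrics call
    single = threshold_sweep(c, grid=[0.4], n_null=10, seed=2)[0]
    g = binarize(c, "sparsity", 0.4)
    direct = graph_metrics(
        g, n_null=10, seed=np.random.default_rng(np.random.SeedSequence([2, 0]))
    )
    assert single == direct
    with pytest.raises(ValueError):
        threshold_sweep(c, grid=[])
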