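"""Spatial graph and neighborhood statistics: oracles, nulls, constructed patterns."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import distance_matrix as dm

from plexcell.spatial import (
    build_graph,
    co_occurrence,
    default_bin_edges,
    interaction_matrix,
    neighborhood_enrichment,
)


# --- build_graph -----------------------------------------------------------

def test_collinear_points_hand_enumeration():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    g = build_graph(coords, k=1)
    assert sorted(map(tuple, g.edges)) == [(0, 1), (1, 2)]


def test_complete_graph_at_k_n_minus_one():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 10, size=(8, 2))
    g = build_graph(coords, k=7)
    assert g.n_edges == 8 * 7 // 2


def test_degree_at_least_k_and_knn_edges_present():
    """Union symmetrization: every node keeps edges to its k nearest
    (brute-force distance oracle), so degree >= k."""
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 100, size=(60, 2))
    k = 5
    g = build_graph(coords, k=k)
    assert g.degrees().min() >= k
    edge_set = set(map(tuple, g.edges))
    d = dm(coords, coords)
    np.fill_diagonal(d, np.inf)
    for i in range(len(coords)):
        for j in np.argsort(d[i])[:k]:
            assert (min(i, j), max(i, j)) in edge_set


def test_no_cross_core_edges():
    rng = np.random.default_rng(2)
    coords = np.vstack([rng.uniform(0, 10, (20, 2)), rng.uniform(100, 110, (20, 2))])
    cores = np.repeat([0, 1], 20)
    g = build_graph(coords, core_ids=cores, k=3)
    assert (cores[g.edges[:, 0]] == cores[g.edges[:, 1]]).all()


def test_small_core_errors_and_duplicate_warns():
    coords = np.zeros((4, 2))
    with pytest.raises(ValueError, match="core"):
        build_graph(coords, core_ids=np.array([0, 0, 1, 1]), k=3)
    with pytest.warns(UserWarning, match="duplicate"):
        build_graph(np.array([[0, 0], [0, 0], [1, 1]], dtype=float), k=1)


# --- neighborhood_enrichment ------------------------------------------------

def grid_graph_checkerboard(n=12):
    yy, xx = np.mgrid[:n, :n]
    coords = np.c_[xx.ravel(), yy.ravel()].astype(float)
    labels = np.where((xx + yy) % 2 == 0, "black", "white").ravel()
    return build_graph(coords, k=4), labels


def test_checkerboard_enrichment_signs():
    g, labels = grid_graph_checkerboard()
    res = neighborhood_enrichment(g, labels, n_permutations=500, seed=0)
    i = res.classes.index("black")
    j = res.classes.index("white")
    assert res.zscore[i, i] < -3 and res.zscore[j, j] < -3
    assert res.zscore[i, j] > 3


def test_null_zscores_are_standard_normal():
    """Random labels on a fixed graph give z ~ N(0,1) over replicates."""
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 100, size=(150, 2))
    g = build_graph(coords, k=4)
    zs = []
    for rep in range(120):
        labels = rng.choice(["a", "b"], size=150)
        res = neighborhood_enrichment(g, labels, n_permutations=150, seed=rep)
        zs.extend(res.zscore[np.triu_indices(2)])
    zs = np.asarray(zs)
    assert abs(zs.mean()) < 0.1
    assert 0.8 < zs.std() < 1.2


def test_two_disconnected_cliques_homotypic():
    coords = np.vstack(
        [np.random.default_rng(4).uniform(0, 1, (6, 2)),
         np.random.default_rng(5).uniform(50, 51, (6, 2))]
    )
    g = build_graph(coords, core_ids=np.repeat([0, 1], 6), k=5)  # two cliques
    labels = np.array(["X"] * 12)
    with pytest.warns(UserWarning, match="zero permutation variance"):
        res = neighborhood_enrichment(g, labels, n_permutations=50, seed=0)
    assert res.observed[0, 0] == g.n_edges
    assert np.isnan(res.zscore[0, 0])  # single class: no variance under null


def test_mixed_cliques_homotypic_positive():
    rng = np.random.default_rng(6)
    coords = np.vstack([rng.uniform(0, 1, (8, 2)), rng.uniform(50, 51, (8, 2))])
    labels = np.array(["X"] * 8 + ["Y"] * 8)
    g = build_graph(coords, core_ids=np.repeat([0, 1], 8), k=7)
    res = neighborhood_enrichment(g, labels, n_permutations=300, seed=0)
    i = res.classes.index("X")
    assert res.observed[i, i] == 28  # all X-X edges inside clique 1
    assert res.zscore[i, i] > 3


def test_unlabeled_node_rejected():
    g, labels = grid_graph_checkerboard(6)
    bad = labels.astype(object)
    bad[0] = np.nan
    with pytest.raises(ValueError, match="labeled"):
        neighborhood_enrichment(g, bad)


# --- interaction_matrix ----------------------------------------------------

def test_path_graph_counts():
    coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
    g = build_graph(coords, k=1)  # edges 0-1, 1-2
    m = interaction_matrix(g, np.array(["X", "Y", "X"]))
    assert m.loc["X", "Y"] == 2
    assert m.loc["X", "X"] == 0
    assert m.loc["Y", "X"] == 2  # symmetric


def test_edge_conservation_random_graphs():
    rng = np.random.default_rng(7)
    for rep in range(3):
        coords = rng.uniform(0, 50, size=(40, 2))
        g = build_graph(coords, k=4)
        labels = rng.choice(list("abc"), size=40)
        m = interaction_matrix(g, labels).to_numpy()
        assert np.triu(m).sum() == g.n_edges
        assert np.array_equal(m, m.T)


def test_single_class_diagonal_is_edge_count():
    rng = np.random.default_rng(8)
    coords = rng.uniform(0, 50, size=(30, 2))
    g = build_graph(coords, k=3)
    m = interaction_matrix(g, np.array(["A"] * 30))
    assert m.loc["A", "A"] == g.n_edges


# --- co_occurrence ---------------------------------------------------------

def test_single_class_scores_one_everywhere():
    rng = np.random.default_rng(9)
    coords = rng.uniform(0, 100, size=(200, 2))
    edges = np.linspace(0, 50, 6)
    res = co_occurrence(coords, np.array(["A"] * 200), edges)
    finite = res.score[0, 0][np.isfinite(res.score[0, 0])]
    assert np.allclose(finite, 1.0)


def test_csr_null_mean_is_one():
    """Uniformly random labels: mean score ~ 1 at every distance bin."""
    rng = np.random.default_rng(10)
    coords = rng.uniform(0, 100, size=(500, 2))
    edges = np.linspace(0, 60, 6)
    scores = []
    for _ in range(100):
        labels = rng.choice(["a", "b"], size=500)
        res = co_occurrence(coords, labels, edges)
        scores.append(res.score[0, 1])
    mean_curve = np.nanmean(np.array(scores), axis=0)
    assert np.all(np.abs(mean_curve - 1.0) < 0.1)


def test_attraction_pattern_sign():
    """Target class planted only within 20 µm of anchors: score > 1 near,
    < 1 far."""
    rng = np.random.default_rng(11)
    anchors = rng.uniform(0, 50, size=(40, 2))
    near = anchors[rng.integers(0, 40, 120)] + rng.uniform(-14, 14, size=(120, 2))
    far = rng.uniform(120, 200, size=(150, 2))
    coords = np.vstack([anchors, near, far])
    labels = np.array(["A"] * 40 + ["B"] * 120 + ["C"] * len(far))
    edges = np.array([0.0, 20.0, 70.0, 300.0])
    res = co_occurrence(coords, labels, edges)
    curve = res.curve("A", "B")
    assert curve[0] > 1.0
    assert curve[-1] < 1.0


def test_rescaling_invariance():
    rng = np.random.default_rng(12)
    coords = rng.uniform(0, 50, size=(120, 2))
    labels = rng.choice(["a", "b", "c"], size=120)
    edges = np.linspace(0, 30, 5)
    r1 = co_occurrence(coords, labels, edges)
    r2 = co_occurrence(coords * 3.0, labels, edges * 3.0)
    assert np.allclose(r1.score, r2.score, equal_nan=True)


def test_per_core_averaging_and_skipping():
    """A core lacking the target class is skipped for that pair."""
    rng = np.random.default_rng(13)
    c0 = rng.uniform(0, 20, size=(30, 2))
    c1 = rng.uniform(100, 120, size=(30, 2))
    coords = np.vstack([c0, c1])
    cores = np.repeat([0, 1], 30)
    labels = np.array(["A"] * 15 + ["B"] * 15 + ["A"] * 30)  # core 1 has no B
    edges = np.linspace(0, 25, 4)
    res = co_occurrence(coords, labels, edges, cores)
    ia, ib = res.classes.index("A"), res.classes.index("B")
    assert res.n_cores_used[ia, ib] == 1
    core0_only = res.per_core[0][ia, ib]
    assert np.allclose(res.score[ia, ib], core0_only, equal_nan=True)


def test_group_recomputation_matches_subtables():
    """Filtering to a group then computing equals computing per pre-filtered
    subtable (primary vs metastatic style comparison)."""
    rng = np.random.default_rng(14)
    coords = rng.uniform(0, 80, size=(160, 2))
    group = np.repeat(["primary", "metastatic"], 80)
    labels = rng.choice(["a", "b"], size=160)
    for gname in ("primary", "metastatic"):
        sel = group == gname
        g_all = build_graph(coords[sel], k=4)
        res_sub = neighborhood_enrichment(g_all, labels[sel], 100, seed=2)
        res_again = neighborhood_enrichment(
            build_graph(coords[sel].copy(), k=4), labels[sel], 100, seed=2
        )
        assert np.allclose(res_sub.zscore, res_again.zscore, equal_nan=True)


def test_default_bins_strictly_increasing():
    rng = np.random.default_rng(15)
    coords = rng.uniform(0, 100, size=(50, 2))
    edges = default_bin_edges(coords, n_bins=50)
    assert len(edges) == 51
    assert np.all(np.diff(edges) > 0)
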