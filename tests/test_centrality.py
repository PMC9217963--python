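"""Centrality and bridge indices against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from symnet.centrality import (bridge_expected_influence, compute_centrality,
                               select_bridges)
from symnet.network import EstimatedNetwork


def _net(W, names=None):
    W = np.asarray(W, dtype=float)
    names = names or [f"X{i + 1}" for i in range(W.shape[0])]
    return EstimatedNetwork(W, np.zeros(W.shape[0]), names)


def _floyd_warshall(W):
    p = W.shape[0]
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(p):
        for j in range(p):
            if i != j and W[i, j] != 0:
                D[i, j] = 1.0 / abs(W[i, j])
    for k in range(p):
        for i in range(p):
            for j in range(p):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _brute_betweenness(W):
    """Enumerate all simple paths per pair; fractional count of shortest
    paths through each intermediate node."""
    p = W.shape[0]
    adj = {i: [j for j in range(p) if W[i, j] != 0] for i in range(p)}
    bc = np.zeros(p)
    for s, t in itertools.combinations(range(p), 2):
        paths = []

        def dfs(node, visited, dist):
            if node == t:
                paths.append((dist, tuple(visited)))
                return
            for nb in adj[node]:
                if nb not in visited:
                    dfs(nb, visited + [nb], dist + 1.0 / abs(W[node, nb]))

        dfs(s, [s], 0.0)
        if not paths:
            continue
        dmin = min(d for d, _ in paths)
        shortest = [pth for d, pth in paths if d <= dmin + 1e-12]
        for v in range(p):
            if v in (s, t):
                continue
            frac = sum(v in pth for pth in shortest) / len(shortest)
            bc[v] += frac
    return bc


class TestBasicIndices:
    def test_two_node_network(self):
        tab = compute_centrality(_net([[0, 0.8], [0.8, 0]]))
        assert tab["strength"].tolist() == [0.8, 0.8]
        assert tab["ei1"].tolist() == [0.8, 0.8]
        assert tab["betweenness"].tolist() == [0.0, 0.0]

    def test_five_node_star_hub_betweenness(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.5
        tab = compute_centrality(_net(W))
        assert tab["betweenness"].iloc[0] == 6.0  # all C(4,2) leaf pairs
        assert np.all(tab["betweenness"].iloc[1:] == 0.0)

    def test_negative_edges_enter_strength_absolutely(self):
        tab = compute_centrality(_net([[0, -0.5], [-0.5, 0]]))
        assert tab["strength"].iloc[0] == 0.5
        assert tab["ei1"].iloc[0] == -0.5

    def test_ei2_definition(self):
        W = np.array([[0, 0.5, 0.0],
                      [0.5, 0, -0.3],
                      [0.0, -0.3, 0]])
        tab = compute_centrality(_net(W))
        ei1 = W.sum(axis=1)
        np.testing.assert_allclose(tab["ei2"].to_numpy(), ei1 + W @ ei1)

    def test_random_8node_path_indices_match_bruteforce(self):
        rng = np.random.default_rng(42)
        W = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.45:
                W[i, j] = W[j, i] = rng.uniform(0.2, 1.5) * rng.choice([-1, 1])
        tab = compute_centrality(_net(W))
        D = _floyd_warshall(W)
        # closeness within components: 1 / sum of finite distances
        for i in range(8):
            finite = [D[i, j] for j in range(8) if j != i and np.isfinite(D[i, j])]
            expected = 1.0 / sum(finite) if finite else 0.0
            assert tab["closeness"].iloc[i] == pytest.approx(expected)
        np.testing.assert_allclose(tab["betweenness"].to_numpy(),
                                   _brute_betweenness(W), atol=1e-9)

    def test_empty_network_warns_and_zeroes_path_indices(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            tab = compute_centrality(_net(np.zeros((3, 3))))
        assert np.all(tab["closeness"] == 0)
        assert np.all(tab["betweenness"] == 0)


class TestBridgeExpectedInfluence:
    def test_isolated_community_node_zero(self):
        # 4 nodes, two communities; node X4 only connects within community
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.7  # cross edge
        W[2, 3] = W[3, 2] = 0.9  # within community 2
        comm = {"X1": "a", "X2": "b", "X3": "b", "X4": "b"}
        bei1, bei2 = bridge_expected_influence(_net(W), comm)
        assert bei1["X4"] == 0.0
        assert bei2["X4"] == 0.0  # neighbor X3 also has no cross edges

    def test_two_singletons_joined(self):
        W = np.array([[0, 0.55], [0.55, 0]])
        bei1, _ = bridge_expected_influence(_net(W), {"X1": "a", "X2": "b"})
        assert bei1.tolist() == [0.55, 0.55]

    def test_six_node_bruteforce_double_sum(self):
        rng = np.random.default_rng(5)
        W = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            if rng.random() < 0.6:
                W[i, j] = W[j, i] = rng.normal()
        names = [f"X{i + 1}" for i in range(6)]
        comm = {n: ("a" if i < 3 else "b") for i, n in enumerate(names)}
        bei1, bei2 = bridge_expected_influence(_net(W), comm)
        for i in range(6):
            outside = [k for k in range(6) if comm[names[k]] != comm[names[i]]]
            exp1 = sum(W[i, k] for k in outside)
            exp2 = exp1 + sum(
                W[i, j] * sum(W[j, k] for k in outside if k != i)
                for j in range(6) if j != i)
            assert bei1.iloc[i] == pytest.approx(exp1)
            assert bei2.iloc[i] == pytest.approx(exp2)

    def test_unassigned_node_rejected(self):
        with pytest.raises(ValueError, match="community"):
            bridge_expected_influence(_net(np.zeros((2, 2))), {"X1": "a"})

    def test_sum_bei1_is_twice_cross_weight(self):
        rng = np.random.default_rng(8)
        W = np.zeros((7, 7))
        for i, j in itertools.combinations(range(7), 2):
            W[i, j] = W[j, i] = rng.normal()
        names = [f"X{i + 1}" for i in range(7)]
        comm = {n: ("a" if i < 4 else "b") for i, n in enumerate(names)}
        bei1, _ = bridge_expected_influence(_net(W), comm)
        cross = sum(W[i, j] for i in range(4) for j in range(4, 7))
        assert bei1.sum() == pytest.approx(2 * cross)


class TestSelectBridges:
    def test_14_nodes_give_4_bridges(self):
        scores = pd.Series(np.arange(14, dtype=float),
                           index=[f"n{i}" for i in range(14)])
        res = select_bridges(scores, 0.25)
        assert res.n_selected == 4
        assert set(res.selected) == {"n13", "n12", "n11", "n10"}

    def test_4_nodes_give_1(self):
        assert select_bridges(pd.Series([0.1, 3.0, 1.0, 2.0])).n_selected == 1

    def test_20_nodes_top5_match_explicit_sort(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.permutation(20).astype(float),
                           index=[f"n{i}" for i in range(20)])
        res = select_bridges(scores, 0.25)
        expected = scores.sort_values(ascending=False).index[:5]
        assert res.selected == list(expected)

    def test_boundary_tie_warns_and_uses_node_order(self):
        scores = pd.Series([5.0, 1.0, 1.0, 0.0],
                           index=["a", "b", "c", "d"])
        with pytest.warns(RuntimeWarning, match="tie"):
            res = select_bridges(scores, 0.5)
        assert res.selected == ["a", "b"]


class TestInvariances:
    def _random_net(self, seed=3, p=7):
        rng = np.random.default_rng(seed)
        W = np.zeros((p, p))
        for i, j in itertools.combinations(range(p), 2):
            if rng.random() < 0.5:
                W[i, j] = W[j, i] = rng.uniform(0.2, 1.2)
        return W

    def test_permutation_equivariance(self):
        W = self._random_net()
        names = [f"X{i + 1}" for i in range(7)]
        comm = {n: ("a" if i < 4 else "b") for i, n in enumerate(names)}
        tab = compute_centrality(_net(W, names), communities=comm)
        perm = np.random.default_rng(1).permutation(7)
        Wp = W[np.ix_(perm, perm)]
        names_p = [names[i] for i in perm]
        tab_p = compute_centrality(_net(Wp, names_p), communities=comm)
        for col in ("strength", "closeness", "betweenness", "ei1", "ei2",
                    "bei1", "bei2"):
            np.testing.assert_allclose(tab_p[col].loc[names].to_numpy(),
                                       tab[col].to_numpy(), atol=1e-12)

    def test_scaling_property(self):
        W = self._random_net(seed=6)
        c = 3.7
        tab1 = compute_centrality(_net(W))
        tab2 = compute_centrality(_net(c * W))
        for col in ("strength", "ei1", "ei1"):
            np.testing.assert_allclose(tab2[col], c * tab1[col])
        np.testing.assert_allclose(tab2["ei2"],
                                   c * tab1["ei1"] + c * c * (W @ W.sum(1)))
        # betweenness ranking unchanged under positive scaling
        assert (tab1["betweenness"].rank().tolist()
                == tab2["betweenness"].rank().tolist())
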