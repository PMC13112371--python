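"""Collaboration networks: strengths, correlations, centrality, archetypes."""

import numpy as np
import pandas as pd
import pytest

from healthnet import (ClassifierThresholds, GravityTensor, binarize,
                       centralization, classify_structure, correlation_matrix,
                       degree_centrality, node_strength_series)
from healthnet.network import CollaborationNetwork, ConstantSeriesWarning


def tensor_from(years, cities, fn):
    n = len(cities)
    vals = np.zeros((len(years), n, n))
    for k, y in enumerate(years):
        for i in range(n):
            for j in range(i + 1, n):
                vals[k, i, j] = vals[k, j, i] = fn(y, i, j)
    return GravityTensor(list(cities), list(years), vals)


def adjacency(a, cities=None):
    a = np.asarray(a, int)
    cities = cities or [f"C{k}" for k in range(a.shape[0])]
    return pd.DataFrame(a, index=cities, columns=cities)


class TestNodeStrength:
    def test_two_city_network_strength_is_the_single_edge(self):
        t = tensor_from([1, 2, 3], ["A", "B"], lambda y, i, j: float(y))
        s = node_strength_series(t)
        assert np.allclose(s.loc["A"], [1, 2, 3])
        assert np.allclose(s.loc["A"], s.loc["B"])

    def test_row_sums(self):
        g = {(0, 1): 1.0, (0, 2): 2.0, (1, 2): 4.0}
        t = tensor_from([1, 2, 3], ["A", "B", "C"],
                        lambda y, i, j: g[(i, j)])
        s = node_strength_series(t)
        assert np.allclose(s[1], [3, 5, 6])

    def test_all_zero_tensor_gives_zero_strengths(self):
        t = tensor_from([1, 2, 3], ["A", "B"], lambda y, i, j: 0.0)
        assert (node_strength_series(t) == 0).all().all()

    def test_fewer_than_three_years_rejected(self):
        t = tensor_from([1, 2], ["A", "B"], lambda y, i, j: 1.0)
        with pytest.raises(ValueError, match="3 years"):
            node_strength_series(t)


class TestCorrelation:
    def test_identical_series_correlate_perfectly(self):
        s = pd.DataFrame([[1, 2, 3], [2, 4, 6]], index=["A", "B"])
        r = correlation_matrix(s)
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_anti_linear_series_correlate_minus_one(self):
        s = pd.DataFrame([[1, 2, 3], [5, 4, 3]], index=["A", "B"])
        assert correlation_matrix(s).loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_scipy_pearson(self):
        from scipy.stats import pearsonr
        rng = np.random.default_rng(0)
        s = pd.DataFrame(rng.normal(size=(4, 10)), index=list("ABCD"))
        r = correlation_matrix(s)
        for i in "ABCD":
            for j in "ABCD":
                expected = pearsonr(s.loc[i], s.loc[j]).statistic
                assert r.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(1)
        s = pd.DataFrame(rng.normal(size=(3, 8)), index=list("ABC"))
        r1 = correlation_matrix(s)
        r2 = correlation_matrix(s * 7.3 + 11.0)
        assert np.allclose(r1, r2)

    def test_constant_series_flagged_missing(self):
        s = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["A", "B"])
        with pytest.warns(ConstantSeriesWarning):
            r = correlation_matrix(s)
        assert np.isnan(r.loc["A", "B"])
        assert r.loc["A", "A"] == 1.0

    def test_literal_pairwise_on_symmetric_tensor_is_identically_one(self):
        rng = np.random.default_rng(2)
        t = tensor_from(range(5), list("ABC"),
                        lambda y, i, j: float(rng.uniform(0.1, 1)))
        r = correlation_matrix(t, mode="literal_pairwise")
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off[~np.isnan(off)], 1.0)

    def test_too_few_time_points_rejected(self):
        s = pd.DataFrame([[1, 2], [3, 4]], index=["A", "B"])
        with pytest.raises(ValueError, match="3 time points"):
            correlation_matrix(s)


class TestBinarizeAndCentrality:
    def test_binarize_thresholds_and_zero_diagonal(self):
        r = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=["A", "B"], columns=["A", "B"])
        g = binarize(r, 0.6)
        assert g.loc["A", "B"] == 1 and g.loc["A", "A"] == 0

    def test_extreme_thresholds(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-0.9, 0.9, (4, 4)); m = (m + m.T) / 2; np.fill_diagonal(m, 1)
        r = pd.DataFrame(m, index=list("ABCD"), columns=list("ABCD"))
        low = binarize(r, -0.95)
        assert low.to_numpy()[~np.eye(4, dtype=bool)].all()
        high = binarize(r, 0.999)
        assert not high.to_numpy().any()

    def test_star_graph_centrality_and_centralization(self):
        star = adjacency([[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]])
        cd = degree_centrality(star)
        assert cd.iloc[0] == pytest.approx(1.0)
        assert np.allclose(cd.iloc[1:], 1 / 3)
        assert centralization(star) == pytest.approx(1.0)

    def test_complete_graph(self):
        a = adjacency(1 - np.eye(5, dtype=int))
        assert np.allclose(degree_centrality(a), 1.0)
        assert centralization(a) == pytest.approx(0.0)

    def test_empty_graph(self):
        a = adjacency(np.zeros((4, 4), int))
        assert (degree_centrality(a) == 0).all()
        assert centralization(a) == pytest.approx(0.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            degree_centrality(adjacency([[0]]))

    def test_matches_networkx_on_random_graphs(self):
        import networkx as nx
        rng = np.random.default_rng(5)
        for n in (3, 4, 5):
            for _ in range(20):
                m = (rng.random((n, n)) < 0.5).astype(int)
                m = np.triu(m, 1); m = m + m.T
                a = adjacency(m)
                ours = degree_centrality(a)
                theirs = nx.degree_centrality(nx.from_numpy_array(m))
                for k in range(n):
                    assert ours.iloc[k] == pytest.approx(theirs[k])


class TestClassifier:
    def _network(self, adj, r=None):
        adj = adjacency(adj)
        if r is None:
            r = adj.astype(float).copy()
            np.fill_diagonal(r.values, 1.0)
        return CollaborationNetwork(
            r=r, adjacency=adj, degree_centrality=degree_centrality(adj),
            centralization=centralization(adj))

    def test_star_with_dominant_uhi_is_unipolar(self):
        net = self._network([[0, 1, 1, 1, 1],
                             [1, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0]])
        uhi = pd.Series([0.9, 0.2, 0.25, 0.22, 0.21], index=net.cities)
        assert classify_structure(net, uhi) == "unipolar"

    def test_complete_graph_with_equal_uhis_never_unipolar(self):
        n = 6
        net = self._network(1 - np.eye(n, dtype=int))
        uhi = pd.Series(0.5, index=net.cities)
        assert classify_structure(net, uhi) in ("indeterminate", "polycentric")

    def test_two_coupled_hubs_is_core_periphery(self):
        adj = np.zeros((6, 6), int)
        adj[0, 1:] = adj[1:, 0] = 1
        adj[1, 2:] = adj[2:, 1] = 1
        net = self._network(adj)
        net.r.iloc[0, 1] = net.r.iloc[1, 0] = 0.9
        uhi = pd.Series([0.9, 0.85, 0.2, 0.2, 0.2, 0.2], index=net.cities)
        assert classify_structure(net, uhi) == "core_periphery"

    def test_two_decoupled_hubs_is_dual_core(self):
        adj = np.zeros((6, 6), int)
        adj[0, [2, 3]] = adj[[2, 3], 0] = 1
        adj[1, [4, 5]] = adj[[4, 5], 1] = 1
        net = self._network(adj)
        net.r.iloc[0, 1] = net.r.iloc[1, 0] = 0.05
        uhi = pd.Series([0.9, 0.85, 0.2, 0.2, 0.2, 0.2], index=net.cities)
        assert classify_structure(net, uhi) == "dual_core_segmented"

    def test_thresholds_are_configurable(self):
        net = self._network([[0, 1, 1, 1, 1],
                             [1, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0],
                             [1, 0, 0, 0, 0]])
        uhi = pd.Series([0.9, 0.2, 0.25, 0.22, 0.21], index=net.cities)
        strict = ClassifierThresholds(unipolar_centralization=1.01)
        assert classify_structure(net, uhi, strict) == "indeterminate"
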