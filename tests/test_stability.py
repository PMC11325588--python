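import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from invanet import stability


def _dense_oracle(g):
    """Independent spectral oracle: plain eigendecomposition + mean exp."""
    a = nx.to_numpy_array(g)
    a = (a != 0).astype(float)
    w = np.linalg.eigvals(a).real
    return float(np.log(np.mean(np.exp(w))))


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        g = nx.empty_graph(7)
        assert stability.natural_connectivity(g) == pytest.approx(0.0, abs=1e-12)

    def test_single_edge(self):
        g = nx.Graph([("a", "b")])
        assert stability.natural_connectivity(g) == pytest.approx(
            math.log(math.cosh(1)), abs=1e-12
        )

    def test_triangle(self):
        g = nx.complete_graph(3)
        expected = math.log((math.e**2 + 2 * math.exp(-1)) / 3)
        assert stability.natural_connectivity(g) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.99631, abs=1e-5)

    def test_signed_weights_ignored(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-0.9)
        assert stability.natural_connectivity(g) == pytest.approx(
            math.log(math.cosh(1)), abs=1e-12
        )

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 31))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.9), seed=int(rng.integers(2**31)))
            assert stability.natural_connectivity(g) == pytest.approx(
                _dense_oracle(g), abs=1e-8
            )

    def test_edge_deletion_never_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(4, 20))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            before = stability.natural_connectivity(g)
            u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
            g.remove_edge(u, v)
            assert stability.natural_connectivity(g) <= before + 1e-12

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            stability.natural_connectivity(nx.Graph())


class TestRobustnessCurve:
    def test_fraction_zero_is_intact_value(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        curve = stability.robustness_curve(g, fractions=[0.0], n_reps=5, seed=0)
        row = curve.table.iloc[0]
        assert row["mean"] == pytest.approx(stability.natural_connectivity(g))
        assert row["sd"] == 0.0

    def test_complete_graph_closed_form(self):
        n, f = 10, 0.35
        g = nx.complete_graph(n)
        m = math.floor(f * n)
        k = n - m
        expected = math.log((math.exp(k - 1) + (k - 1) * math.exp(-1)) / k)
        curve = stability.robustness_curve(g, fractions=[f], n_reps=4, seed=1)
        row = curve.table.iloc[0]
        assert row["mean"] == pytest.approx(expected, abs=1e-10)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_curve_non_increasing_on_er_graphs(self):
        g = nx.gnp_random_graph(60, 0.1, seed=3)
        curve = stability.robustness_curve(
            g, fractions=np.arange(0, 0.81, 0.1), n_reps=20, seed=4
        )
        means = curve.table["mean"].to_numpy()
        sds = curve.table["sd"].to_numpy()
        # non-increasing within Monte-Carlo noise of one SD
        assert ((np.diff(means) <= sds[1:] + 1e-9)).all()

    def test_determinism_under_seed(self):
        g = nx.gnp_random_graph(20, 0.2, seed=5)
        c1 = stability.robustness_curve(g, n_reps=3, seed=9)
        c2 = stability.robustness_curve(g, n_reps=3, seed=9)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_invalid_fractions_rejected(self):
        g = nx.complete_graph(4)
        with pytest.raises(ValueError):
            stability.robustness_curve(g, fractions=[1.0], n_reps=1)


def _brute_force_connectedness(table):
    """Exhaustive per-pair oracle: mean correlation over every
    permutation of the partner column, subtracted from the observed."""
    rel = table.div(table.sum(axis=1), axis=0).to_numpy()
    n, t = rel.shape
    corr = np.corrcoef(rel, rowvar=False)
    null = np.zeros((t, t))
    for i in range(t):
        for j in range(t):
            if i == j:
                continue
            vals = []
            for perm in itertools.permutations(range(n)):
                vals.append(np.corrcoef(rel[:, i], rel[list(perm), j])[0, 1])
            null[i, j] = np.mean(vals)
    corrected = corr - null
    np.fill_diagonal(corrected, 0.0)
    pos = np.zeros(t)
    neg = np.zeros(t)
    for i in range(t):
        row = np.delete(corrected[i], i)
        pos[i] = row[row > 0].mean() if (row > 0).any() else 0.0
        neg[i] = row[row < 0].mean() if (row < 0).any() else 0.0
    return pos, neg


class TestConnectednessAndCohesion:
    def test_single_taxon_is_zero(self):
        table = pd.DataFrame({"t": [3, 4, 5, 6, 7]})
        conn = stability.connectedness(table, n_null=10, seed=0)
        assert conn.loc["t", "pos"] == 0.0 and conn.loc["t", "neg"] == 0.0

    def test_identical_profiles_connectedness_near_one(self):
        # two proportional taxa plus a filler keeping library size fixed,
        # so the pair stays perfectly correlated after normalisation
        x = np.array([10, 20, 30, 40, 50, 60, 25, 35, 45, 15])
        table = pd.DataFrame({"a": x, "b": x, "filler": 200 - 2 * x})
        conn = stability.connectedness(table, n_null=500, seed=0)
        assert conn.loc["a", "pos"] == pytest.approx(1.0, abs=0.05)
        assert conn.loc["b", "pos"] == pytest.approx(1.0, abs=0.05)

    def test_exhaustive_matches_brute_force_oracle(self, rng):
        table = pd.DataFrame(
            rng.integers(1, 40, size=(6, 3)), columns=["a", "b", "c"]
        )
        conn = stability.connectedness(table, n_null=1, exhaustive=True)
        pos, neg = _brute_force_connectedness(table)
        assert np.allclose(conn["pos"].to_numpy(), pos, atol=1e-10)
        assert np.allclose(conn["neg"].to_numpy(), neg, atol=1e-10)

    def test_n_null_validation(self):
        table = pd.DataFrame(np.ones((5, 2)))
        with pytest.raises(ValueError):
            stability.connectedness(table, n_null=0)

    def test_zero_connectedness_gives_zero_cohesion(self, toy_counts):
        conn = pd.DataFrame(
            {"pos": [0.0] * 3, "neg": [0.0] * 3}, index=toy_counts.columns
        )
        coh = stability.cohesion(toy_counts, conn)
        assert (coh == 0).all().all()

    def test_perfectly_cooperative_pair_cohesion_near_one(self):
        x = np.array([10, 20, 30, 40, 50, 60, 25, 35, 45, 15])
        table = pd.DataFrame({"a": x, "b": x})
        conn = pd.DataFrame({"pos": [1.0, 1.0], "neg": [0.0, 0.0]}, index=["a", "b"])
        coh = stability.cohesion(table, conn)
        # sum of abundances is 1, so C+ = 1 regardless of the split
        assert np.allclose(coh["pos_cohesion"], 1.0)

    def test_cohesion_scale_invariance(self, toy_counts, rng):
        conn = pd.DataFrame(
            {"pos": rng.uniform(size=3), "neg": -rng.uniform(size=3)},
            index=toy_counts.columns,
        )
        coh1 = stability.cohesion(toy_counts, conn)
        coh2 = stability.cohesion(toy_counts * 2, conn)
        pd.testing.assert_frame_equal(coh1, coh2)

    def test_taxon_mismatch_rejected(self, toy_counts):
        conn = pd.DataFrame({"pos": [0.1], "neg": [-0.1]}, index=["other"])
        with pytest.raises(ValueError, match="taxon"):
            stability.cohesion(toy_counts, conn)
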