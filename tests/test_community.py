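import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from invanet import community, diversity


def _euclidean_dm(points, ids=None):
    d = squareform(pdist(points))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(d, ids=ids)


class TestNMDS:
    def test_collinear_points_embed_with_near_zero_stress(self):
        points = np.linspace(0, 1, 8)[:, None] * np.array([[1.0, 2.0]])
        res = community.nmds(_euclidean_dm(points), k=2, n_restarts=10, seed=0)
        assert res.stress < 0.01
        assert res.converged

    def test_degenerate_equal_dissimilarities(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.warns(UserWarning, match="degenerate"):
            res = community.nmds(DistanceMatrix(d, ids=list("abcde")))
        assert res.stress == 0.0

    def test_shepard_relationship_monotone(self, rng):
        from sklearn.isotonic import IsotonicRegression

        table = pd.DataFrame(rng.integers(1, 50, size=(10, 25)))
        dm = diversity.bray_curtis(table)
        res = community.nmds(dm, n_restarts=20, seed=1)
        emb = pdist(res.coordinates.to_numpy())
        orig = dm.condensed_form()
        # independent isotonic fit of configuration distances on the
        # dissimilarity ranks: fitted disparities must be non-decreasing
        # and reproduce the reported Kruskal stress-1
        ranks = stats.rankdata(orig)
        iso = IsotonicRegression(increasing=True)
        dhat = iso.fit_transform(ranks, emb)
        order = np.argsort(orig)
        assert (np.diff(dhat[order]) >= -1e-12).all()
        stress_check = np.sqrt(((emb - dhat) ** 2).sum() / (emb**2).sum())
        assert res.stress == pytest.approx(stress_check, abs=0.05)
        # and the embedding is strongly rank-correlated with the input
        assert stats.spearmanr(orig, emb).statistic > 0.5

    def test_restart_stability_across_seeds(self, rng):
        table = pd.DataFrame(rng.integers(1, 50, size=(10, 25)))
        dm = diversity.bray_curtis(table)
        stresses = [
            community.nmds(dm, n_restarts=20, seed=s).stress for s in (0, 1, 2)
        ]
        assert max(stresses) - min(stresses) < 1e-3


def _brute_force_anosim(d, labels):
    """Independent enumeration oracle for the n=6, 3+3 design."""
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(d[iu])
    rank_mat = np.zeros_like(d)
    rank_mat[iu] = ranks
    rank_mat += rank_mat.T
    m = n * (n - 1) // 2

    def r_stat(lab):
        within, between = [], []
        for i in range(n):
            for j in range(i + 1, n):
                (within if lab[i] == lab[j] else between).append(rank_mat[i, j])
        return (np.mean(between) - np.mean(within)) / (m / 2)

    obs = r_stat(labels)
    stats_all = []
    for combo in itertools.combinations(range(n), 3):
        lab = np.zeros(n, dtype=int)
        lab[list(combo)] = 1
        stats_all.append(r_stat(lab))
    # each split appears twice among distinct label assignments
    stats_all = np.array(stats_all + stats_all)
    return obs, np.mean(stats_all >= obs - 1e-12)


class TestAnosim:
    def test_fully_separated_gives_r_one(self):
        points = np.concatenate([np.zeros((4, 2)), 10 + np.zeros((4, 2))])
        points += np.arange(8)[:, None] * 0.01
        dm = _euclidean_dm(points)
        labels = ["a"] * 4 + ["b"] * 4
        res = community.anosim(dm, labels, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_equal_dissimilarities_give_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = community.anosim(dm, ["a"] * 3 + ["b"] * 3, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_p_matches_brute_force(self, rng):
        points = rng.normal(size=(6, 3))
        dm = _euclidean_dm(points)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = community.anosim(dm, labels, seed=0)
        obs, p_oracle = _brute_force_anosim(dm.data, labels)
        assert res.exhaustive
        assert res.statistic == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_statistic_matches_skbio(self, rng):
        points = rng.normal(size=(12, 4))
        dm = _euclidean_dm(points)
        labels = ["a"] * 6 + ["b"] * 6
        ours = community.anosim(dm, labels, seed=0)
        ref = skbio_anosim(dm, np.array(labels), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-12)


class TestPermanova:
    def test_hand_ss_decomposition(self):
        d = np.array(
            [
                [0, 1, 2, 4, 4, 4],
                [1, 0, 1, 4, 4, 4],
                [2, 1, 0, 4, 4, 4],
                [4, 4, 4, 0, 1, 2],
                [4, 4, 4, 1, 0, 1],
                [4, 4, 4, 2, 1, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        # oracle: SS_total = sum d^2 / n over all pairs, SS_within per group
        ss_total = (d[np.triu_indices(6, 1)] ** 2).sum() / 6
        ss_within = 2 * ((1 + 4 + 1) / 3)
        f_oracle = (ss_total - ss_within) / 1 / (ss_within / 4)
        res = community.permanova(dm, labels, seed=0)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert res.effect_size == pytest.approx(1 - ss_within / ss_total, abs=1e-10)

    def test_two_identical_clusters_r2_one(self):
        points = np.concatenate([np.zeros((3, 2)), np.ones((3, 2))])
        dm = _euclidean_dm(points)
        res = community.permanova(dm, ["a"] * 3 + ["b"] * 3, seed=0)
        assert res.effect_size == pytest.approx(1.0)

    def test_statistic_matches_skbio(self, rng):
        points = rng.normal(size=(12, 4))
        dm = _euclidean_dm(points)
        labels = ["a"] * 5 + ["b"] * 7
        ours = community.permanova(dm, labels, seed=0)
        ref = skbio_permanova(dm, np.array(labels), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_reordering_invariance(self, rng):
        points = rng.normal(size=(10, 3))
        dm = _euclidean_dm(points)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        ids = np.array(dm.ids)
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=list(ids[perm]))
        r1 = community.permanova(dm, labels, seed=3)
        r2 = community.permanova(dm2, labels[perm], seed=3)
        a1 = community.anosim(dm, labels, seed=3)
        a2 = community.anosim(dm2, labels[perm], seed=3)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert a1.statistic == pytest.approx(a2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert a1.p_value == pytest.approx(a2.p_value, abs=1e-12)

    def test_group_of_one_rejected(self, rng):
        dm = _euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            community.permanova(dm, ["a", "b", "b", "b", "b"], seed=0)


class TestWithinGroupDissimilarities:
    def test_counts_and_size_two_group(self, rng):
        points = rng.normal(size=(7, 2))
        dm = _euclidean_dm(points)
        labels = ["a", "a", "b", "b", "b", "b", "b"]
        out = community.within_group_dissimilarities(dm, labels)
        assert len(out["a"]) == 1
        assert len(out["b"]) == 10
        assert out["a"][0] == pytest.approx(dm["s0", "s1"])


class TestTaxaCovariateCorrelations:
    def _fixture(self, rng, n=12):
        ab = pd.DataFrame(
            rng.uniform(size=(n, 3)),
            index=[f"s{i}" for i in range(n)],
            columns=["p1", "p2", "p3"],
        )
        md = pd.DataFrame(
            {"cov1": ab["p1"].to_numpy(), "cov2": rng.normal(size=n)},
            index=ab.index,
        )
        return ab, md

    def test_perfect_and_negated_correlation(self, rng):
        ab, md = self._fixture(rng)
        rho, p, q = community.taxa_covariate_correlations(ab, md)
        assert rho.loc["p1", "cov1"] == pytest.approx(1.0)
        md2 = md.assign(cov1=-md["cov1"])
        rho2, _, _ = community.taxa_covariate_correlations(ab, md2)
        assert rho2.loc["p1", "cov1"] == pytest.approx(-rho.loc["p1", "cov1"])

    def test_independent_covariate_not_significant(self, rng):
        ab, md = self._fixture(rng, n=20)
        _, _, q = community.taxa_covariate_correlations(ab, md[["cov2"]])
        assert (q["cov2"] > 0.05).mean() >= 2 / 3

    def test_constant_covariate_masked(self, rng):
        ab, md = self._fixture(rng)
        md["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            rho, p, q = community.taxa_covariate_correlations(ab, md[["flat"]])
        assert rho["flat"].isna().all()
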