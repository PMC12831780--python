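import numpy as np
import pandas as pd
import pytest

from spheroid_ith import (
    GeneSetCollection,
    ValidationError,
    pca,
    rank_normalize,
    ssgsea_score,
    ssgsea_score_matrix,
    top_pathways,
)
from conftest import make_matrix


def ssgsea_oracle(values: dict[str, float], gene_set, exponent: float) -> float:
    """Independent running-sum transcription of the weighted-ECDF score."""
    genes = sorted(values, key=lambda g: (-values[g], g))
    hits = [g in set(gene_set) for g in genes]
    w = [abs(values[g]) ** exponent if h else 0.0 for g, h in zip(genes, hits)]
    total_w = sum(w)
    n_out = hits.count(False)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for wi, h in zip(w, hits):
        cum_in += wi / total_w
        cum_out += (not h) / n_out
        score += cum_in - cum_out
    return score


class TestPCA:
    def test_collinear_samples_single_component(self):
        # two proteins, samples lying exactly on a line in protein space
        vals = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        res = pca(make_matrix(vals, scale="log2"), n_components=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_scores_are_isometric(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(20, 2, (30, 8)), scale="log2")
        res = pca(m, n_components=8)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(res.scores.to_numpy()), pdist(Xc))
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(20, 2, (30, 6)), scale="log2")
        r1 = pca(m, n_components=3)
        r2 = pca(m, n_components=3)
        assert r1.scores.equals(r2.scores)
        for c in r1.loadings.columns:
            col = r1.loadings[c]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_excessive_components_rejected(self):
        m = make_matrix(np.ones((5, 3)), scale="log2")
        with pytest.raises(ValueError):
            pca(m, n_components=4)

    def test_planted_size_clusters_recovered(self):
        import spheroid_ith as si
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        for seed in (1, 2, 3):
            cfg = si.SimulationConfig(
                seed=seed,
                lines={"L": si.LineConfig(n_spheroids=18)},
                n_drivers=0,
                cluster_count=3,
            )
            cohort = si.simulate_cohort(cfg)
            matrix, _ = si.simulate_protein_matrix(cfg, cohort)
            filtered, _ = si.preprocess_matrix(matrix, min_proteins=1)
            res = pca(filtered, n_components=2)
            order = np.argsort([r.diameter_um for r in cohort], kind="stable")
            truth = np.empty(len(cohort), dtype=int)
            for g, grp in enumerate(np.array_split(order, 3)):
                truth[grp] = g
            labels = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(
                res.scores.to_numpy()
            )
            assert adjusted_rand_score(truth, labels) > 0.8


class TestRankNormalize:
    def test_rank_over_size(self):
        out = rank_normalize(pd.Series({"a": 5.0, "b": 1.0, "c": 3.0}))
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1 / 3)
        assert out["c"] == pytest.approx(2 / 3)

    def test_ties_get_average_rank(self):
        out = rank_normalize(pd.Series({"a": 2.0, "b": 2.0}))
        assert np.allclose(out, 0.75)

    def test_idempotent_up_to_rescaling(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        once = rank_normalize(s)
        twice = rank_normalize(once)
        assert np.allclose(once, twice)


class TestSsgseaScore:
    def _profile(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.uniform(0.1, 10, n), index=[f"g{i}" for i in range(n)])

    def test_top_ranked_set_positive_bottom_negative(self):
        profile = pd.Series(
            {"g1": 10.0, "g2": 9.0, "g3": 2.0, "g4": 1.0, "g5": 0.5}
        )
        assert ssgsea_score(profile, {"g1", "g2"}) > 0
        assert ssgsea_score(profile, {"g4", "g5"}) < 0

    def test_hand_enumerated_four_gene_example(self):
        profile = pd.Series({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        # set {g1, g3}, exponent 0: in-ECDF (.5, .5, 1, 1), out (0, .5, .5, 1)
        assert ssgsea_score(profile, {"g1", "g3"}, weight_exponent=0.0) == (
            pytest.approx(1.0)
        )

    @pytest.mark.parametrize("exponent", [0.0, 0.25, 1.0])
    def test_matches_independent_oracle(self, exponent):
        profile = self._profile(seed=3)
        gene_set = {"g2", "g5", "g11", "g17"}
        assert ssgsea_score(profile, gene_set, exponent) == pytest.approx(
            ssgsea_oracle(profile.to_dict(), gene_set, exponent)
        )

    def test_rank_invariance_at_zero_exponent(self):
        profile = self._profile(seed=4)
        gene_set = {"g1", "g7", "g13"}
        s1 = ssgsea_score(profile, gene_set, 0.0)
        s2 = ssgsea_score(np.exp(profile / 3), gene_set, 0.0)
        assert s1 == pytest.approx(s2)

    def test_degenerate_sets_rejected(self):
        profile = self._profile()
        with pytest.raises(ValidationError):
            ssgsea_score(profile, set(profile.index))
        with pytest.raises(ValidationError):
            ssgsea_score(profile, {"absent_gene"})

    def test_random_set_mean_score_near_zero(self):
        # exchangeable ranks make the rank-based (exponent 0) score
        # mean-zero over random profiles
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        scores = []
        for _ in range(1000):
            profile = pd.Series(rng.permutation(40).astype(float) + 1, index=genes)
            scores.append(ssgsea_score(profile, set(genes[:8]), 0.0))
        scores = np.asarray(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * se


class TestScoreMatrixAndTopPathways:
    def _scores(self):
        expr = pd.DataFrame(
            {
                "s1": [10.0, 8.0, 2.0, 1.0, 5.0, 3.0],
                "s2": [1.0, 2.0, 9.0, 10.0, 5.0, 3.0],
            },
            index=[f"g{i}" for i in range(6)],
        )
        coll = GeneSetCollection(
            {"up_in_s1": ["g0", "g1"], "up_in_s2": ["g2", "g3"], "flat": ["g4", "g5"]}
        )
        return ssgsea_score_matrix(expr, coll), coll

    def test_one_score_per_sample_set_pair(self):
        scores, _ = self._scores()
        assert scores.scores.shape == (3, 2)
        assert np.isfinite(scores.scores.to_numpy()).all()

    def test_top_pathways_orders_by_spread(self):
        scores, coll = self._scores()
        top = top_pathways(scores, n=1)
        assert len(top) == 1
        assert top.iloc[0]["pathway"] in ("up_in_s1", "up_in_s2")
        everything = top_pathways(scores, n=10)
        assert list(everything["pathway"])[-1] == "flat"

    def test_redundant_sets_collapsed(self):
        expr = pd.DataFrame(
            {"s1": np.arange(10, 0, -1, dtype=float),
             "s2": np.arange(1, 11, dtype=float)},
            index=[f"g{i}" for i in range(10)],
        )
        coll = GeneSetCollection(
            {
                "big": [f"g{i}" for i in range(5)],
                "subset_of_big": [f"g{i}" for i in range(4)],  # 100% overlap
                "other": ["g7", "g8", "g9"],
            }
        )
        scores = ssgsea_score_matrix(expr, coll)
        top = top_pathways(scores, n=3, collection=coll)
        names = set(top["pathway"])
        assert not {"big", "subset_of_big"} <= names
        assert "other" in names
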