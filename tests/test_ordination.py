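import numpy as np
import pytest
from scipy.spatial.distance import squareform, pdist

from gutpredict.ordination import (
    clr_transform,
    groupwise_tests,
    pca_scores,
    permanova,
    zscore,
)


class TestClr:
    def test_uniform_row_is_zero(self):
        out = clr_transform(np.full((3, 4), 0.25))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_hand_example(self):
        out = clr_transform(np.array([[0.5, 0.25, 0.25]]))
        np.testing.assert_allclose(out.values[0], [0.462, -0.231, -0.231], atol=1e-3)

    def test_rows_sum_to_zero(self, rng):
        X = rng.dirichlet(np.ones(20), size=10)
        out = clr_transform(X)
        np.testing.assert_allclose(out.values.sum(axis=1), 0.0, atol=1e-9)

    def test_taxon_permutation_equivariance(self, rng):
        X = rng.dirichlet(np.ones(6), size=5)
        perm = rng.permutation(6)
        a = clr_transform(X).values[:, perm]
        b = clr_transform(X[:, perm]).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zeros_need_pseudocount(self):
        X = np.array([[0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(X, pseudocount=0.0)
        out = clr_transform(X)  # default: half the smallest nonzero value
        assert np.isfinite(out.values).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[-0.1, 1.1]]))


def _two_clusters(rng, n_per=8, sep=10.0, dim=4):
    a = rng.normal(0.0, 1.0, size=(n_per, dim))
    b = rng.normal(sep, 1.0, size=(n_per, dim))
    X = np.vstack([a, b])
    groups = np.array(["A"] * n_per + ["B"] * n_per)
    return X, groups


class TestPermanova:
    def test_separated_clusters_minimal_p(self, rng):
        X, groups = _two_clusters(rng)
        D = squareform(pdist(X))
        res = permanova(D, groups, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_lower_bound(self, rng):
        X, groups = _two_clusters(rng, sep=0.0)
        D = squareform(pdist(X))
        res = permanova(D, groups, n_permutations=99, seed=1)
        assert res.p_value >= 1 / 100

    def test_sample_order_invariance(self, rng):
        X, groups = _two_clusters(rng, sep=2.0)
        D = squareform(pdist(X))
        res = permanova(D, groups, n_permutations=9, seed=0)
        perm = rng.permutation(len(groups))
        D2 = D[np.ix_(perm, perm)]
        res2 = permanova(D2, groups[perm], n_permutations=9, seed=0)
        assert res2.pseudo_f == pytest.approx(res.pseudo_f, abs=1e-10)

    def test_small_group_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(D, ["A", "A", "B"])

    def test_asymmetric_matrix_rejected(self, rng):
        D = rng.random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            permanova(D, ["A", "A", "B", "B"])

    def test_type_one_error_near_nominal(self, rng):
        # null: labels carry no information; rejection rate at 0.05 stays small
        hits = 0
        n_sim = 120
        for i in range(n_sim):
            X = rng.normal(size=(15, 4))
            groups = np.array(["A"] * 8 + ["B"] * 7)
            D = squareform(pdist(X))
            res = permanova(D, groups, n_permutations=99, seed=i)
            hits += res.p_value <= 0.05
        assert 0.005 <= hits / n_sim <= 0.12


class TestGroupwiseTests:
    def test_separated_taxon_minimal_exact_p(self, rng):
        # fully separated 8-vs-7 split: two-sided exact p = 2 / C(15, 8)
        x = np.concatenate([np.arange(8) + 100.0, np.arange(7)])
        X = np.column_stack([x, rng.normal(size=15)])
        groups = np.array(["PS"] * 8 + ["NS"] * 7)
        out = groupwise_tests(
            __import__("pandas").DataFrame(X, columns=["sep", "noise"]), groups
        )
        from math import comb

        expected = 2 / comb(15, 8)
        assert out.set_index("taxon_id").loc["sep", "p_value"] == pytest.approx(expected)

    def test_q_values_monotone_in_p(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(15, 30)))
        X.columns = [f"t{j}" for j in range(30)]
        groups = np.array(["PS"] * 8 + ["NS"] * 7)
        out = groupwise_tests(X, groups).sort_values("p_value")
        assert (out["q_value"].diff().dropna() >= -1e-12).all()

    def test_all_tied_taxon_warns(self, rng):
        import pandas as pd

        X = pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)})
        groups = np.array(["A"] * 5 + ["B"] * 5)
        with pytest.warns(UserWarning, match="tied"):
            out = groupwise_tests(X, groups)
        assert out.set_index("taxon_id").loc["flat", "p_value"] == 1.0

    def test_null_false_rejection_controlled(self, rng):
        import pandas as pd

        false_hits = []
        for i in range(60):
            X = pd.DataFrame(rng.normal(size=(15, 40)))
            X.columns = [f"t{j}" for j in range(40)]
            groups = np.array(["A"] * 8 + ["B"] * 7)
            out = groupwise_tests(X, groups, fdr=0.05)
            false_hits.append((out["q_value"] < 0.05).sum())
        assert np.mean(false_hits) < 0.5

    def test_two_groups_required(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="two groups"):
            groupwise_tests(X, np.array(["A", "A", "B", "B", "C", "C"]))


class TestZscore:
    def test_mean_zero_unit_sd(self, rng):
        X = rng.normal(3.0, 2.0, size=(12, 5))
        Z = zscore(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(10, 3))
        np.testing.assert_allclose(zscore(5 * X + 2), zscore(X), atol=1e-10)

    def test_hand_example_sample_sd(self):
        np.testing.assert_allclose(zscore(np.array([[1.0], [2.0], [3.0]])).ravel(), [-1, 0, 1])

    def test_constant_column_warns_and_zeroes(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            Z = zscore(X)
        np.testing.assert_array_equal(Z[:, 0], 0.0)


class TestPca:
    def test_variance_fractions_sum_to_one(self, rng):
        out = pca_scores(rng.normal(size=(10, 6)))
        assert out["variance_explained"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_sample_same_scores(self, rng):
        X = rng.normal(size=(8, 5))
        X2 = np.vstack([X, X[3]])
        out = pca_scores(X2)
        np.testing.assert_allclose(out["scores"][3], out["scores"][-1], atol=1e-10)

    def test_two_clusters_separate_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        X, groups = _two_clusters(rng, sep=8.0)
        out = pca_scores(X)
        pc1 = out["scores"][:, :1]
        assert silhouette_score(pc1, groups) > 0.5

    def test_orthonormal_loadings(self, rng):
        out = pca_scores(rng.normal(size=(12, 5)))
        L = out["loadings"]
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_needs_two_taxa(self, rng):
        with pytest.raises(ValueError):
            pca_scores(rng.normal(size=(5, 1)))
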