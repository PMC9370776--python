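import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gutpredict.mc_search import (
    MCSettings,
    SingularDesignError,
    aicc_from_rss,
    average_ranks,
    compute_index,
    fit_ols,
    reduce_and_iterate,
    sample_models,
)


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(3)
    n, p = 15, 8
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, 0] - 1.5 * X[:, 3] + rng.normal(scale=0.5, size=n)
    ids = [f"t{j}" for j in range(p)]
    return pd.DataFrame(X, columns=ids), y


class TestFitOls:
    def test_four_terms_has_six_parameters(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        fit = fit_ols(X, y)
        assert fit.n_params == 6

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(15, 3))
        beta_true = np.array([1.0, -2.0, 0.5])
        y = X @ beta_true + rng.normal(scale=0.3, size=15)
        fit = fit_ols(X, y)
        A = np.column_stack([np.ones(15), X])
        beta_oracle = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(
            np.concatenate([[fit.intercept], fit.coef]), beta_oracle, atol=1e-8
        )

    def test_exact_fit_floors_rss_with_warning(self, rng):
        X = rng.normal(size=(10, 1))
        y = 2.0 * X[:, 0] + 1.0
        with pytest.warns(UserWarning, match="floor"):
            fit = fit_ols(X, y)
        assert fit.rss == 1e-12
        assert np.isfinite(fit.aicc)

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=12)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularDesignError):
            fit_ols(X, rng.normal(size=12))

    def test_too_many_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ols(rng.normal(size=(8, 5)), rng.normal(size=8))

    def test_aicc_formula(self):
        # n * ln(RSS/n) + 2k + 2k(k+1)/(n-k-1) at n=15, 4 terms (k=6)
        expected = 15 * math.log(10.0 / 15) + 12 + 84 / 8
        assert aicc_from_rss(10.0, 15, 4) == pytest.approx(expected)


class TestSampleModels:
    def test_single_term_pool(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 1)), columns=["only"])
        settings = MCSettings(n_models=10, max_terms=1, seed=0)
        pool = sample_models(["only"], settings, X, rng.normal(size=10))
        assert pool.n_models == 1
        assert pool.terms_of(0) == (0,)

    def test_full_coverage_of_small_space(self, design):
        X, y = design
        # p=6, max_terms=3: C(6,1)+C(6,2)+C(6,3) = 41 distinct subsets
        terms = list(X.columns[:6])
        settings = MCSettings(n_models=5000, max_terms=3, seed=1)
        pool = sample_models(terms, settings, X, y)
        assert pool.n_models == 41
        seen = {tuple(sorted(pool.terms_of(i))) for i in range(pool.n_models)}
        assert len(seen) == 41

    def test_deterministic(self, design):
        X, y = design
        settings = MCSettings(n_models=300, max_terms=3, seed=5)
        a = sample_models(list(X.columns), settings, X, y)
        b = sample_models(list(X.columns), settings, X, y)
        np.testing.assert_array_equal(a.flat_terms, b.flat_terms)
        np.testing.assert_array_equal(a.aicc, b.aicc)

    def test_pool_smaller_than_max_terms_rejected(self, design):
        X, y = design
        with pytest.raises(ValueError, match="max_terms"):
            sample_models(["t0", "t1"], MCSettings(max_terms=4), X, y)

    def test_batch_fit_matches_single_fits(self, design):
        X, y = design
        settings = MCSettings(n_models=100, max_terms=3, seed=2)
        pool = sample_models(list(X.columns), settings, X, y)
        for i in range(0, pool.n_models, 7):
            cols = list(pool.terms_of(i))
            single = fit_ols(X.to_numpy()[:, cols], y)
            assert pool.aicc[i] == pytest.approx(single.aicc, abs=1e-8)


class TestComputeIndex:
    def test_single_taxon_index_is_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 1)), columns=["only"])
        settings = MCSettings(n_models=10, max_terms=1, seed=0)
        pool = sample_models(["only"], settings, X, rng.normal(size=10))
        table = compute_index(pool, settings)
        assert table["index"].iloc[0] == 1.0

    def test_stage_max_is_one_under_any_weighting(self, design):
        X, y = design
        pool = sample_models(list(X.columns), MCSettings(n_models=500, seed=3), X, y)
        for w in [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.45, 0.10, 0.45)]:
            table = compute_index(pool, MCSettings(weights=w))
            assert table["index"].max() == pytest.approx(1.0)

    def test_signal_terms_rank_top(self, design):
        X, y = design
        settings = MCSettings(n_models=2000, seed=4)
        pool = sample_models(list(X.columns), settings, X, y)
        table = compute_index(pool, settings).set_index("taxon_id")
        assert table.loc["t0", "rank"] <= 2
        assert table.loc["t3", "rank"] <= 2

    def test_relabeling_invariance(self, design):
        X, y = design
        settings = MCSettings(n_models=800, seed=6)
        table = compute_index(sample_models(list(X.columns), settings, X, y), settings)
        renamed = X.rename(columns={c: f"z_{c}" for c in X.columns})
        table2 = compute_index(
            sample_models(list(renamed.columns), settings, renamed, y), settings
        )
        merged = table.assign(taxon_id="z_" + table.taxon_id).merge(
            table2, on="taxon_id", suffixes=("_a", "_b")
        )
        np.testing.assert_allclose(merged["index_a"], merged["index_b"], atol=1e-12)

    def test_ranks_are_midrank_permutation(self, design):
        X, y = design
        settings = MCSettings(n_models=500, seed=8)
        table = compute_index(sample_models(list(X.columns), settings, X, y), settings)
        assert table["rank"].sum() == pytest.approx(len(table) * (len(table) + 1) / 2)


class TestReduceAndIterate:
    def test_no_reduction_single_stage(self, design):
        X, y = design
        settings = MCSettings(n_models=300, seed=1, reduction_schedule=None)
        result = reduce_and_iterate(list(X.columns), X, y, settings)
        assert len(result.stage_tables) == 1
        assert result.stage_sizes == [8]

    def test_stage_sizes_follow_schedule(self, small_pm, small_cohort):
        y = small_cohort.outcomes.rwl
        settings = MCSettings(
            n_models=1500, seed=2, reduction_schedule=(102, 44, 23, 15, 7)
        )
        result = reduce_and_iterate(list(small_pm.taxon_ids), small_pm, y, settings)
        assert result.stage_sizes == [102, 44, 23, 15, 7]
        assert [len(t) for t in result.stage_tables] == [102, 44, 23, 15, 7]
        assert len(result.final_terms) == 7

    def test_schedule_exceeding_pool_rejected(self, design):
        X, y = design
        settings = MCSettings(n_models=100, reduction_schedule=(20, 5), seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            reduce_and_iterate(list(X.columns), X, y, settings)

    def test_increasing_schedule_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            MCSettings(reduction_schedule=(10, 12, 5))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MCSettings(weights=(0.5, 0.2, 0.2))


class TestOracleEquivalence:
    def test_best_per_size_matches_exhaustive(self, rng):
        # oracle: enumerate every subset with independent single fits
        n, p, max_terms = 15, 8, 3
        for _ in range(5):
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            ids = [f"v{j}" for j in range(p)]
            df = pd.DataFrame(X, columns=ids)
            total = sum(math.comb(p, k) for k in range(1, max_terms + 1))
            settings = MCSettings(n_models=total * 20, max_terms=max_terms, seed=0)
            pool = sample_models(ids, settings, df, y)
            best = pool.best_by_size()
            for k in range(1, max_terms + 1):
                oracle_best = min(
                    (
                        (fit_ols(X[:, list(combo)], y).aicc, tuple(ids[j] for j in combo))
                        for combo in itertools.combinations(range(p), k)
                    ),
                )
                assert best[k][0] == oracle_best[1]
                assert best[k][1] == pytest.approx(oracle_best[0], abs=1e-8)


class TestAverageRanks:
    def _table(self, pairs):
        return pd.DataFrame(
            {"taxon_id": [p[0] for p in pairs], "rank": [p[1] for p in pairs]}
        )

    def test_unanimous_rank_one(self):
        full = [self._table([("a", 1), ("b", 2)]), self._table([("a", 1), ("b", 2)])]
        final = [self._table([("a", 1)]), self._table([("a", 1)])]
        out = average_ranks(full, final)
        assert out.loc["a", "avg_rank_full"] == 1.0
        assert out.loc["a", "avg_rank_final"] == 1.0

    def test_fractional_average(self):
        full = [self._table([("a", 2)]), self._table([("a", 3)])]
        out = average_ranks(full, [])
        assert out.loc["a", "avg_rank_full"] == 2.5

    def test_missing_marker_propagates(self):
        full = [self._table([("a", 1), ("b", 2)])]
        final = [self._table([("a", 1)])]
        out = average_ranks(full, final)
        assert np.isnan(out.loc["b", "avg_rank_final"])

    def test_requires_full_tables(self):
        with pytest.raises(ValueError):
            average_ranks([], [])


@pytest.mark.slow
def test_monotone_signal_strength(small_pm):
    # raising a taxon's association with y never worsens its median rank
    rng = np.random.default_rng(0)
    X = small_pm.to_dataframe().iloc[:, :30]
    target = X.columns[5]
    medians = []
    for strength in (0.0, 0.5, 1.0):
        ranks = []
        for seed in range(15):
            noise = rng.standard_normal(len(X))
            y = strength * (X[target] - X[target].mean()).to_numpy() / X[target].std() + noise
            settings = MCSettings(n_models=800, seed=seed)
            table = compute_index(
                sample_models(list(X.columns), settings, X, y), settings
            ).set_index("taxon_id")
            ranks.append(table.loc[target, "rank"])
        medians.append(np.median(ranks))
    assert medians[2] <= medians[1] <= medians[0] + 5
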