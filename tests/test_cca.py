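import numpy as np
import pandas as pd
import pytest

from prosocial import PlantedStructure, generate_trait_cohort
from prosocial.cca import (
    ROLE_COLLINEAR,
    ROLE_CONTRIBUTOR,
    ROLE_NEGLIGIBLE,
    ROLE_SUPPRESSOR,
    classify_roles,
    commonality,
    fit_cca,
    permutation_test,
    select_commonality_predictors,
    wilks_sequential_test,
)
from prosocial.traits import TRAIT_NAMES

from oracles import cca_first_corr_bruteforce, commonality_regression_oracle


def _data(n=120, p=5, q=2, seed=0, shared=0.6):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    X = shared * z[:, None] + rng.standard_normal((n, p))
    Y = shared * z[:, None] + rng.standard_normal((n, q))
    return X, Y


class TestFitCCA:
    def test_number_of_functions_is_smaller_set_size(self):
        X, Y = _data(n=200, p=18, q=2)
        res = fit_cca(X, Y)
        assert len(res.correlations) == 2

    def test_identical_subsets_give_unit_correlations(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 4))
        Y = X[:, :2].copy()
        res = fit_cca(X, Y)
        assert res.correlations == pytest.approx([1.0, 1.0], abs=1e-8)

    def test_first_correlation_matches_direct_maximization(self):
        X, Y = _data(n=50, p=3, q=2, seed=7)
        res = fit_cca(X, Y)
        brute = cca_first_corr_bruteforce(X, Y, seed=1)
        assert res.correlations[0] == pytest.approx(brute, abs=1e-4)

    def test_agrees_with_sklearn(self):
        from sklearn.cross_decomposition import CCA as SkCCA

        X, Y = _data(n=150, p=6, q=2, seed=3)
        res = fit_cca(X, Y)
        sk = SkCCA(n_components=2, scale=True, max_iter=2000).fit(X, Y)
        u, v = sk.transform(X, Y)
        sk_r = [abs(np.corrcoef(u[:, k], v[:, k])[0, 1]) for k in range(2)]
        assert res.correlations == pytest.approx(sk_r, abs=1e-6)

    def test_cross_loading_identity(self):
        X, Y = _data(seed=5)
        res = fit_cca(X, Y)
        for k in range(len(res.correlations)):
            expected = res.x_loadings[:, k] * res.correlations[k]
            assert np.allclose(res.x_cross_loadings[:, k], expected, atol=1e-10)
            # and cross-loadings really are correlations with the opposite variate
            direct = [
                np.corrcoef(np.asarray(X, float)[:, j], res.y_scores[:, k])[0, 1]
                for j in range(X.shape[1])
            ]
            assert np.allclose(res.x_cross_loadings[:, k], direct, atol=1e-10)

    def test_variates_unit_variance_and_orthogonal(self):
        X, Y = _data(seed=6)
        res = fit_cca(X, Y)
        for scores in (res.x_scores, res.y_scores):
            cov = np.cov(scores, rowvar=False, ddof=1)
            assert np.allclose(cov, np.eye(scores.shape[1]), atol=1e-10)

    def test_single_criterion_reduces_to_multiple_correlation(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 4))
        y = X @ np.array([0.5, -0.3, 0.2, 0.0]) + rng.standard_normal(100)
        res = fit_cca(X, y[:, None])
        beta, *_ = np.linalg.lstsq(
            np.c_[np.ones(100), X], y, rcond=None
        )
        yhat = np.c_[np.ones(100), X] @ beta
        mult_r = np.corrcoef(y, yhat)[0, 1]
        assert res.correlations[0] == pytest.approx(mult_r, abs=1e-10)

    def test_univariate_case_is_absolute_pearson(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(60)
        y = -0.7 * x + rng.standard_normal(60)
        res = fit_cca(x[:, None], y[:, None])
        assert res.correlations[0] == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-12)
        assert abs(res.x_weights[0, 0]) == pytest.approx(1.0, abs=1e-10)
        assert abs(res.y_weights[0, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_anchors_first_y_loading_positive(self):
        for seed in range(5):
            X, Y = _data(seed=seed)
            res = fit_cca(X, Y)
            assert np.all(res.y_loadings[0, :] >= 0)

    def test_rank_deficiency_error_names_columns(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        X["c"] = X["a"] * 2.0
        Y = pd.DataFrame(rng.standard_normal((50, 2)), columns=["u", "v"])
        with pytest.raises(ValueError, match="a|c"):
            fit_cca(X, Y)


class TestWilksSequential:
    def test_degrees_of_freedom_for_18_by_2_design(self):
        table = wilks_sequential_test([0.37, 0.30], n=325, p=18, q=2)
        assert (table.loc[0, "df1"], table.loc[0, "df2"]) == (36.0, 610.0)
        assert (table.loc[1, "df1"], table.loc[1, "df2"]) == (17.0, 306.0)

    def test_null_correlations_give_unit_lambda_zero_f(self):
        table = wilks_sequential_test([0.0, 0.0], n=100, p=5, q=2)
        assert (table["wilks_lambda"] == 1.0).all()
        assert (table["F"] == 0.0).all()
        assert table["p"].to_numpy() == pytest.approx(1.0)

    def test_lambda_is_product_of_residual_terms(self):
        r = [0.6, 0.4, 0.1]
        table = wilks_sequential_test(r, n=200, p=8, q=3)
        assert table.loc[0, "wilks_lambda"] == pytest.approx(
            (1 - 0.36) * (1 - 0.16) * (1 - 0.01)
        )
        assert table.loc[2, "wilks_lambda"] == pytest.approx(1 - 0.01)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            wilks_sequential_test([0.2, 0.5], n=100, p=4, q=2)


class TestPermutation:
    def test_reproducible_given_seed(self):
        X, Y = _data(seed=11)
        a = permutation_test(X, Y, n_perm=200, seed=42)
        b = permutation_test(X, Y, n_perm=200, seed=42)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null, b.null)

    def test_statistic_is_largest_squared_correlation(self):
        X, Y = _data(seed=12)
        res = fit_cca(X, Y)
        perm = permutation_test(X, Y, n_perm=200, seed=0)
        assert perm.statistic == pytest.approx(res.correlations[0] ** 2, abs=1e-10)

    def test_paired_shuffle_leaves_statistic_unchanged(self):
        # permuting X and Y rows identically only relabels participants
        X, Y = _data(seed=13)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(X))
        a = permutation_test(X, Y, n_perm=200, seed=1)
        b = permutation_test(X[order], Y[order], n_perm=200, seed=1)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_strong_association_detected(self):
        X, Y = _data(n=300, seed=14, shared=1.0)
        assert permutation_test(X, Y, n_perm=200, seed=2).p_value < 0.01

    def test_too_few_permutations_rejected(self):
        X, Y = _data()
        with pytest.raises(ValueError):
            permutation_test(X, Y, n_perm=50)


class TestCommonality:
    def test_orthogonal_predictors_have_no_common_variance(self):
        rng = np.random.default_rng(15)
        n = 4000
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = 0.5 * x1 + 0.3 * x2 + rng.standard_normal(n)
        out = commonality(np.c_[x1, x2], y)
        assert np.allclose(out["common"], 0.0, atol=0.01)
        assert np.allclose(out["unique"], out["total"], atol=0.01)

    def test_partition_matches_regression_oracle(self):
        rng = np.random.default_rng(16)
        n, k = 400, 10
        L = rng.normal(scale=0.4, size=(k, k))
        X = rng.standard_normal((n, k)) @ (np.eye(k) + L)
        y = X @ rng.normal(scale=0.3, size=k) + rng.standard_normal(n)
        ours = commonality(X, y)
        oracle = commonality_regression_oracle(
            (X - X.mean(0)) / X.std(0, ddof=1), (y - y.mean()) / y.std(ddof=1)
        )
        assert np.allclose(ours[["unique", "common", "total"]].to_numpy(), oracle, atol=1e-10)

    def test_unique_plus_common_equals_total(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((200, 6))
        y = X @ rng.normal(size=6) + rng.standard_normal(200)
        out = commonality(X, y)
        assert np.allclose(out["unique"] + out["common"], out["total"], atol=1e-12)

    def test_suppressor_shows_negative_common_and_tiny_total(self):
        # x2 is uncorrelated with the criterion but shares noise with x1
        rng = np.random.default_rng(18)
        n = 50_000
        noise = rng.standard_normal(n)
        x1 = rng.standard_normal(n) + noise
        x2 = noise + 0.3 * rng.standard_normal(n)
        y = (x1 - noise) + 0.5 * rng.standard_normal(n)
        out = commonality(np.c_[x1, x2], y).set_index(pd.Index(["x1", "x2"], name="v"))
        assert out.loc["x2", "total"] < 0.01
        assert out.loc["x2", "common"] < -0.05

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(19)
        with pytest.raises(ValueError):
            commonality(rng.standard_normal((30, 21)), rng.standard_normal(30))


class TestRoles:
    @pytest.mark.parametrize(
        "loading, weight, role",
        [
            (0.8, 0.7, ROLE_CONTRIBUTOR),
            (0.6, 0.05, ROLE_COLLINEAR),
            (0.1, 0.5, ROLE_SUPPRESSOR),
            (0.1, 0.1, ROLE_NEGLIGIBLE),
            (-0.4, -0.35, ROLE_CONTRIBUTOR),
        ],
    )
    def test_threshold_classification(self, loading, weight, role):
        assert classify_roles([loading], [weight])[0] == role

    def test_predictor_selection_uses_either_threshold(self):
        idx = select_commonality_predictors([0.5, 0.1, 0.05], [0.05, 0.4, 0.1])
        assert list(idx) == [0, 1]

    def test_planted_traits_classified_as_contributing(self):
        planted = PlantedStructure()
        nonzero = set(planted.loadings)
        good, total = 0, 0
        for s in range(30):
            traits, gt = generate_trait_cohort(325, planted, seed=1000 + s)
            res = fit_cca(
                traits[list(TRAIT_NAMES)], gt[["hyperaltruism", "prosocial_effort"]]
            )
            roles = classify_roles(res.x_loadings[:, 0], res.x_weights[:, 0])
            for name, role in zip(TRAIT_NAMES, roles):
                if name in nonzero:
                    total += 1
                    good += role in (ROLE_CONTRIBUTOR, ROLE_COLLINEAR)
        assert good / total >= 0.9
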