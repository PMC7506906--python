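import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from itug.errors import PreprocessingError, SchemaError
from itug.plsr import (
    FeatureTable,
    classify_vip,
    explained_variation,
    fit_pls1,
    predict,
    rmsep,
    vip,
)


def _random_table(n=30, m=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    y = X[:, 0] - 0.5 * X[:, 1] + 0.3 * rng.normal(size=n)
    return FeatureTable(pd.DataFrame(X, columns=[f"f{j}" for j in range(m)]),
                        pd.Series(y))


class TestFitPls1:
    def test_single_informative_column_is_fully_explained(self):
        # zero-mean mutually orthogonal columns (sinusoids at distinct
        # harmonics); the response is exactly linear in one of them
        i = np.arange(16)
        X = np.column_stack([np.sin(2 * np.pi * k * i / 16) for k in (1, 2, 3, 4)])
        y = 2.0 * X[:, 2]
        table = FeatureTable(pd.DataFrame(X), pd.Series(y))
        model = fit_pls1(table, 1)
        assert explained_variation(model)[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_fit_equals_ordinary_least_squares(self):
        table = _random_table(10, 4, seed=7)
        model = fit_pls1(table, 4)
        A = np.column_stack([np.ones(10), table.X.to_numpy()])
        beta, *_ = np.linalg.lstsq(A, table.y.to_numpy(), rcond=None)
        np.testing.assert_allclose(
            predict(model, table.X, model.a_max), A @ beta, atol=1e-8
        )

    def test_first_weight_is_proportional_to_correlations(self):
        table = _random_table(40, 6, seed=3)
        model = fit_pls1(table, 2)
        Xs = (table.X - table.X.mean()) / table.X.std(ddof=1)
        cov = Xs.to_numpy().T @ (table.y - table.y.mean()).to_numpy()
        np.testing.assert_allclose(
            model.W[:, 0], cov / np.linalg.norm(cov), atol=1e-10
        )

    def test_scores_are_orthogonal_and_weights_unit_norm(self):
        model = fit_pls1(_random_table(25, 8, seed=5), 5)
        G = model.T.T @ model.T
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.diag(G).max()
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12)

    def test_zero_variance_column_is_named(self):
        table = _random_table(20, 4, seed=1)
        X = table.X.copy()
        X["f2"] = 3.14
        with pytest.raises(PreprocessingError, match="f2"):
            fit_pls1(FeatureTable(X, table.y), 2)

    def test_excessive_component_count_rejected(self):
        with pytest.raises(ValueError):
            fit_pls1(_random_table(10, 4), 10)


class TestPredict:
    def test_column_mismatch_is_schema_error(self):
        model = fit_pls1(_random_table(20, 5), 2)
        with pytest.raises(SchemaError):
            predict(model, np.zeros((3, 4)), 1)

    def test_training_means_predict_response_mean(self):
        table = _random_table(30, 6, seed=2)
        model = fit_pls1(table, 4)
        for a in (0, 1, 4):
            out = predict(model, table.X.mean().to_numpy()[None, :], a)
            assert out[0] == pytest.approx(table.y.mean(), abs=1e-10)


class TestExplainedVariation:
    def test_components_sum_to_ols_r2(self):
        table = _random_table(18, 6, seed=11)
        model = fit_pls1(table, 6)
        A = np.column_stack([np.ones(18), table.X.to_numpy()])
        beta, *_ = np.linalg.lstsq(A, table.y.to_numpy(), rcond=None)
        resid = table.y.to_numpy() - A @ beta
        r2_ols = 1 - resid @ resid / np.sum((table.y - table.y.mean()) ** 2)
        assert explained_variation(model).sum() == pytest.approx(r2_ols, abs=1e-10)

    def test_non_negative_and_bounded(self):
        ev = explained_variation(fit_pls1(_random_table(25, 8, seed=4), 6))
        assert (ev >= -1e-12).all()
        assert ev.sum() <= 1 + 1e-12


class TestRmsep:
    def test_identical_vectors_score_zero(self):
        assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset_gives_its_magnitude(self):
        y = np.arange(5.0)
        assert rmsep(y, y - 3.0) == pytest.approx(3.0)

    def test_matches_brute_force(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        assert rmsep(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsep([1.0], [1.0, 2.0])


class TestVip:
    def test_single_feature_has_unit_vip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        table = FeatureTable(pd.DataFrame({"only": x}), pd.Series(2 * x))
        np.testing.assert_allclose(vip(fit_pls1(table, 1), 1), [1.0])

    def test_orthogonal_predictors_hand_computed(self):
        X = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0],
                      [0, 1], [0, -1], [0, 1], [0, -1]])
        table = FeatureTable(pd.DataFrame(X), pd.Series(X[:, 0]))
        np.testing.assert_allclose(
            vip(fit_pls1(table, 1), 1), [np.sqrt(2), 0.0], atol=1e-12
        )

    @given(st.integers(0, 200))
    def test_squared_vips_sum_to_feature_count(self, seed):
        table = _random_table(seed=seed)
        model = fit_pls1(table, 4)
        for a in (1, 2, 4):
            v = vip(model, a)
            assert np.sum(v**2) == pytest.approx(table.m, abs=1e-8)

    def test_column_permutation_permutes_vips(self, rng):
        table = _random_table(seed=9)
        perm = rng.permutation(table.m)
        permuted = FeatureTable(table.X.iloc[:, perm], table.y)
        v0 = vip(fit_pls1(table, 3), 3)
        v1 = vip(fit_pls1(permuted, 3), 3)
        np.testing.assert_allclose(v1, v0[perm], atol=1e-10)


class TestClassifyVip:
    @pytest.mark.parametrize("value,band", [
        (1.123, "1-1.21"),   # a published mid-band VIP
        (0.785, "below 0.83"),
        (1.0, "1-1.21"),     # boundary goes to the upper bin
        (0.83, "0.83-1"),
        (1.21, "above 1.21"),
        (1.5, "above 1.21"),
    ])
    def test_banding(self, value, band):
        assert classify_vip([value]) == [band]
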