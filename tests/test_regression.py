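"""PLSR (R2/Q2/VIP), MLR, the sorted 2:1 split, and correlation ranking."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenoscreen.errors import DomainError, InsufficientDataError
from phenoscreen.regression import (
    MultiLinearRegression,
    PLSRegressionVIP,
    rank_marker_correlations,
    select_significant_vips,
    split_train_validation,
)
from phenoscreen.simulate import (
    RegressionSpec,
    SimulationConfig,
    simulate_regression_dataset,
)


def zscore(a):
    a = np.asarray(a, dtype=float)
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def centered_orthonormal(n: int, p: int, seed: int = 0) -> np.ndarray:
    """Orthonormal columns with zero column means (so centering inside
    the PLS core is a no-op)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q


class TestPLSRFit:
    def test_noiseless_rank_one_perfect_fit(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(20)
        X = np.outer(t, rng.standard_normal(5))  # rank-1 signal
        y = X @ np.array([1.0, 0.5, 0, 0, -0.2])
        model = PLSRegressionVIP(n_components=1).fit(X, y)
        assert model.r2_ == pytest.approx(1.0)

    def test_pure_noise_q2_nonpositive(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        model = PLSRegressionVIP(n_components=2).fit(X, y)
        assert model.q2_ <= 0

    def test_orthonormal_first_weight_aligns_with_informative_column(self):
        X = centered_orthonormal(12, 5)
        y = X[:, 0].copy()
        model = PLSRegressionVIP(n_components=1).fit(X, y)
        w = model._pls.x_weights_[:, 0]
        cosine = abs(w[0]) / np.linalg.norm(w)
        assert cosine > 0.999

    def test_constant_response_rejected(self):
        with pytest.raises(DomainError):
            PLSRegressionVIP(n_components=1).fit(np.eye(5), np.ones(5))

    def test_full_rank_components_reproduce_ols(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        pls = PLSRegressionVIP(n_components=4).fit(X, y)
        ols = MultiLinearRegression().fit(X, y)
        np.testing.assert_allclose(pls.predict(X), ols.predict(X), atol=1e-8)

    def test_loocv_deterministic(self, regression_config):
        X, y, _ = simulate_regression_dataset(regression_config)
        a = PLSRegressionVIP(n_components=2).fit(zscore(X), zscore(y))
        b = PLSRegressionVIP(n_components=2).fit(zscore(X), zscore(y))
        assert a.q2_ == b.q2_
        np.testing.assert_array_equal(a.loocv_predictions_, b.loocv_predictions_)

    def test_q2_strong_signal_n8(self, regression_config):
        """At the eight-sample scale with a strong planted linear signal
        and noise sd 0.1, LOOCV Q2 exceeds 0.8."""
        X, y, _ = simulate_regression_dataset(regression_config)
        model = PLSRegressionVIP().fit(zscore(X), zscore(y))
        assert model.q2_ > 0.8

    def test_q2_not_above_r2(self):
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed,
                regression=RegressionSpec(
                    n_samples=12, n_features=6, rank=2, noise_sd=0.3
                ),
            )
            X, y, _ = simulate_regression_dataset(cfg)
            m = PLSRegressionVIP(n_components=2).fit(zscore(X), zscore(y))
            assert m.q2_ <= m.r2_ + 1e-12


class TestVIP:
    def test_normalization_identity_across_models(self):
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed,
                regression=RegressionSpec(
                    n_samples=10, n_features=7, rank=3, noise_sd=0.2
                ),
            )
            X, y, _ = simulate_regression_dataset(cfg)
            m = PLSRegressionVIP(n_components=2).fit(zscore(X), zscore(y))
            assert (m.vip_**2).sum() == pytest.approx(X.shape[1])

    def test_single_relevant_predictor_gets_sqrt_p(self):
        X = centered_orthonormal(12, 6)
        y = X[:, 2].copy()
        m = PLSRegressionVIP(n_components=1).fit(X, y)
        assert abs(m.vip_[2]) == pytest.approx(np.sqrt(6), rel=1e-6)
        others = np.delete(m.vip_, 2)
        np.testing.assert_allclose(np.abs(others), 0.0, atol=1e-6)

    def test_anticorrelated_predictor_negative_sign(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        X = np.column_stack([-x, rng.standard_normal(30)])
        y = x.copy()
        m = PLSRegressionVIP(n_components=1).fit(X, y)
        assert m.vip_[0] < 0

    @pytest.mark.parametrize(
        "vip, p, included",
        [(1.0, 0.01, False), (2.0, 0.2, False), (1.5, 0.01, True),
         (-1.5, 0.01, True)],
    )
    def test_selection_rule(self, vip, p, included):
        chosen = select_significant_vips(np.array([vip]), np.array([p]))
        assert (0 in chosen) is included


class TestSplit:
    @pytest.mark.parametrize(
        "n, n_train, n_val",
        [(21, 14, 7), (6, 4, 2), (7, 5, 2), (3, 2, 1)],
    )
    def test_sorted_two_to_one_sizes(self, n, n_train, n_val):
        rng = np.random.default_rng(n)
        train, val = split_train_validation(
            [f"s{i}" for i in range(n)], rng.standard_normal(n)
        )
        assert (len(train), len(val)) == (n_train, n_val)
        assert not set(train) & set(val)

    def test_every_third_sorted_sample_validates(self):
        y = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.0])
        ids = list("abcdef")
        train, val = split_train_validation(ids, y)
        order = [ids[i] for i in np.argsort(y)]
        assert val == [order[2], order[5]]

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            split_train_validation(["a", "b"], [1.0, 2.0])


class TestMLR:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((14, 4))
        beta = np.array([1.0, -2.0, 0.5, 0.0])
        y = X @ beta + 1.5
        m = MultiLinearRegression().fit(X, y)
        np.testing.assert_allclose(m.coef_, beta, atol=1e-12)
        assert m.intercept_ == pytest.approx(1.5)
        # predictions on training data reproduce fitted values
        np.testing.assert_allclose(m.predict(X), y, atol=1e-12)

    def test_coefficient_rmse_under_noise(self):
        """n=14, p=4, noise sd 0.1: coefficient RMSE over 500 fits stays
        below 0.1 (theory: ~ sd/sqrt(n) ~ 0.03 per coefficient)."""
        beta = np.array([1.0, -0.5, 0.25, 0.0])
        errs = []
        rng = np.random.default_rng(5)
        for _ in range(500):
            X = rng.standard_normal((14, 4))
            y = X @ beta + rng.normal(0, 0.1, 14)
            m = MultiLinearRegression().fit(X, y)
            errs.append(np.mean((m.coef_ - beta) ** 2))
        rmse = np.sqrt(np.mean(errs))
        assert rmse < 0.1

    def test_singular_design_names_columns(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0),
                             np.random.default_rng(6).standard_normal(10)])
        with pytest.raises(DomainError, match="collinear"):
            MultiLinearRegression().fit(X, np.arange(10.0))

    def test_validation_correlation_on_split(self):
        cfg = SimulationConfig(
            seed=9,
            regression=RegressionSpec(
                n_samples=21, n_features=4, rank=4, noise_sd=0.1,
                coefficients=(1.0, -0.5, 0.25, 0.1),
            ),
        )
        X, y, _ = simulate_regression_dataset(cfg)
        train, val = split_train_validation(list(X.index), y.to_numpy())
        m = MultiLinearRegression().fit(X.loc[train], y.loc[train])
        r, p = m.validate(X.loc[val], y.loc[val])
        assert r > 0.95 and p < 0.05


class TestMarkerCorrelations:
    @staticmethod
    def _proteins(n=20, p=30, seed=7):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, p))
        cols = [f"P{i}" for i in range(p)]
        return pd.DataFrame(zscore(data), columns=cols)

    def test_target_equals_protein_tops_ranking(self):
        prot = self._proteins()
        prot["mirror"] = prot["P0"] - prot["P1"]
        out = rank_marker_correlations(prot, "P0", "P1", named=["mirror"])
        top = out.iloc[0]
        assert top["protein"] == "mirror"
        assert top["r"] == pytest.approx(1.0)
        assert top["percentile"] == 100.0

    def test_negated_target_bottom(self):
        prot = self._proteins()
        prot["anti"] = prot["P1"] - prot["P0"]
        out = rank_marker_correlations(prot, "P0", "P1")
        bottom = out.iloc[-1]
        assert bottom["protein"] == "anti"
        assert bottom["r"] == pytest.approx(-1.0)
        assert bottom["percentile"] == 0.0

    def test_independent_noise_near_zero(self):
        prot = self._proteins(n=500, p=4, seed=8)
        out = rank_marker_correlations(prot, "P0", "P1")
        assert out["r"].abs().max() < 0.15

    def test_constant_column_excluded(self):
        prot = self._proteins(n=10, p=4)
        prot["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = rank_marker_correlations(prot, "P0", "P1")
        assert "flat" not in set(out["protein"])
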