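"""PLS core, component selection, metrics, resampling ensemble."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dualfov.chemometrics import (
    _coef_path,
    cross_condition_validate,
    fit_pls,
    metrics,
    run_ensemble,
    select_ncomp,
)
from dualfov.errors import ValidationError


def ols_oracle(X_train, y_train, X_test):
    """Independent normal-equations least squares with intercept."""
    Xc = X_train - X_train.mean(axis=0)
    yc = y_train - y_train.mean()
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    return (X_test - X_train.mean(axis=0)) @ beta + y_train.mean()


class TestMetrics:
    def test_perfect(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r_squared == pytest.approx(1.0) and m.rmse == 0.0

    def test_offset_distinguishes_r2_from_rmse(self):
        y = np.array([1.0, 2.0, 3.0])
        m = metrics(y, y + 2.0)
        assert m.r_squared == pytest.approx(1.0) and m.rmse == pytest.approx(2.0)

    def test_hand_computed_rmse(self):
        m = metrics([10.0, 20.0, 30.0], [12.0, 18.0, 33.0])
        assert m.rmse == pytest.approx(np.sqrt(17.0 / 3.0), abs=1e-6)
        assert m.rmse == pytest.approx(2.3805, abs=1e-4)

    def test_zero_variance_flagged(self):
        m = metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(m.r_squared)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            metrics([1.0], [1.0, 2.0])


class TestFitPls:
    def test_single_band_signal_one_component(self):
        rng = np.random.default_rng(0)
        n = 30
        X = np.full((n, 5), 0.3)
        X[:, 2] = rng.uniform(0, 1, n)
        y = 3.0 * X[:, 2] + 1.0
        model = fit_pls(X, y, 1)
        m = metrics(y, model.predict(X))
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        perm = rng.permutation(25)
        a = fit_pls(X, y, 3)
        b = fit_pls(X[perm], y[perm], 3)
        assert np.allclose(a.coef, b.coef, atol=1e-12)

    def test_duplicated_band_equivalent_to_deduplicated_ols(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        y = 2.0 * a - b + rng.normal(0, 0.1, 30)
        X_dup = np.column_stack([a, b, b])
        model = fit_pls(X_dup, y, 2)  # rank of X_dup is 2
        pred = model.predict(X_dup)
        oracle = ols_oracle(np.column_stack([a, b]), y,
                            np.column_stack([a, b]))
        assert np.allclose(pred, oracle, atol=1e-8)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.normal(size=(30, 8))
            y = rng.normal(size=30)
            model = fit_pls(X, y, 8)
            assert np.allclose(
                model.predict(X), ols_oracle(X, y, X), atol=1e-8
            )

    def test_excess_components_capped_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="reduced"):
            model = fit_pls(X, y, 10)
        assert model.n_components == 3

    def test_nan_bands_mean_imputed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        X[3, 1] = np.nan
        model = fit_pls(X, y, 2)
        assert 1 in model.imputed_bands
        assert np.all(np.isfinite(model.predict(X)))


class TestCoefPath:
    def test_truncations_match_separate_fits(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        coefs, x_mean, y_mean = _coef_path(X, y, 6)
        for k, coef in enumerate(coefs, start=1):
            direct = fit_pls(X, y, k)
            pred_path = (X - x_mean) @ coef + y_mean
            assert np.allclose(pred_path, direct.predict(X), atol=1e-8)


class TestSelectNcomp:
    def test_exact_rank_signal_selected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3))
        w = np.array([1.0, -2.0, 0.5])
        y = X @ w
        Xcv = rng.normal(size=(20, 3))
        k = select_ncomp(X, y, Xcv, Xcv @ w, max_components=8)
        assert k == 3

    def test_tie_breaks_to_smallest(self):
        # duplicated band: rank 3, so 3 and 4 components tie at ~zero
        # cv error and the smaller count wins
        rng = np.random.default_rng(8)
        base = rng.normal(size=(60, 3))
        X = np.column_stack([base, base[:, 2]])
        w = np.array([1.0, -2.0, 0.5])
        y = base @ w
        cv_base = rng.normal(size=(20, 3))
        Xcv = np.column_stack([cv_base, cv_base[:, 2]])
        k = select_ncomp(X, y, Xcv, cv_base @ w, max_components=4)
        assert k == 3

    def test_planted_three_component_structure(self):
        # latent-rank-3 spectra with noise: selection lands on 3 +- 1 in
        # at least 90% of seeds
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n, p = 150, 20
            T = rng.normal(size=(n, 3))
            P = rng.normal(size=(p, 3))
            X = T @ P.T + rng.normal(0, 0.3, (n, p))
            y = T @ np.array([2.0, -1.0, 1.5]) + rng.normal(0, 0.3, n)
            idx = rng.permutation(n)
            cal, cv = idx[:110], idx[110:]
            k = select_ncomp(X[cal], y[cal], X[cv], y[cv], max_components=10)
            hits += 2 <= k <= 4
        assert hits >= 0.9 * n_seeds

    def test_invalid_max_components(self):
        with pytest.raises(ValidationError):
            select_ncomp(np.zeros((5, 2)), np.zeros(5), np.zeros((2, 2)),
                         np.zeros(2), max_components=0)


class TestRunEnsemble:
    def _linear_problem(self, n=60, p=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, p))
        w = rng.normal(size=p)
        y = X @ w + 10.0 + rng.normal(0, noise, n)
        return X, y

    def test_noise_free_perfect_signal(self):
        X, y = self._linear_problem()
        res = run_ensemble(X, y, iterations=20, seed=1)
        agg = res.metrics["validation_aggregated"]
        assert agg["r_squared"] == pytest.approx(1.0, abs=1e-8)
        assert agg["rmse"] < 1e-6
        held = res.per_sample["n_times_held_out"] > 0
        assert np.all(res.per_sample.loc[held, "sd_predicted"] < 1e-6)

    def test_seeded_determinism(self):
        X, y = self._linear_problem(noise=0.5)
        a = run_ensemble(X, y, iterations=10, seed=5)
        b = run_ensemble(X, y, iterations=10, seed=5)
        pd.testing.assert_frame_equal(a.per_sample, b.per_sample)
        assert a.metrics == b.metrics

    def test_holdout_bookkeeping(self):
        n = 80
        X, y = self._linear_problem(n=n, noise=0.3)
        iters = 100
        res = run_ensemble(X, y, iterations=iters, seed=2)
        held = res.per_sample["n_times_held_out"]
        # every iteration holds out exactly round(0.25 n) samples
        assert held.sum() == iters * round(0.25 * n)
        assert held.mean() == pytest.approx(iters * 0.25, abs=1e-12)
        assert held.min() > 5

    def test_seed_stability_of_validation_r2(self):
        rng = np.random.default_rng(9)
        n, p = 224, 20
        X = rng.uniform(0, 1, (n, p))
        w = rng.normal(size=p)
        y = X @ w + rng.normal(0, 0.3 * np.std(X @ w), n)
        r2 = [
            run_ensemble(X, y, iterations=50, seed=s).metrics["validation"][
                "r_squared"
            ]
            for s in (1, 2)
        ]
        assert abs(r2[0] - r2[1]) < 0.05

    def test_never_held_out_warns(self):
        X, y = self._linear_problem(n=16)
        with pytest.warns(UserWarning, match="never held out"):
            res = run_ensemble(X, y, iterations=1, seed=0)
        missing = res.per_sample["n_times_held_out"] == 0
        assert missing.any()
        assert res.per_sample.loc[missing, "mean_predicted"].isna().all()

    def test_fixed_validation_topology(self):
        X, y = self._linear_problem(noise=0.2)
        res = run_ensemble(
            X, y, iterations=10, seed=3, topology="fixed-validation"
        )
        held = res.per_sample["n_times_held_out"]
        assert set(held.unique()) == {0, 10}

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            run_ensemble(np.zeros((8, 3)), np.zeros(8))


class TestCrossCondition:
    def test_overlapping_plots_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).uniform(size=(20, 4)),
                         index=[f"p{i}" for i in range(20)])
        y = np.arange(20.0)
        with pytest.raises(ValidationError):
            cross_condition_validate(X, y, X.iloc[:5], y[:5], iterations=2)

    def test_external_predictions_reported(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (40, 5))
        w = rng.normal(size=5)
        y = X @ w + 5.0
        res = cross_condition_validate(
            X[:25], y[:25], X[25:], y[25:],
            train_ids=np.arange(25), test_ids=np.arange(25, 40),
            iterations=10, seed=4,
        )
        agg = res.metrics["external_aggregated"]
        assert agg["r_squared"] == pytest.approx(1.0, abs=1e-8)
        assert len(res.external) == 15
        assert (res.external["n_times_held_out"] == 10).all()
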