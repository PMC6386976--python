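"""PLSR core and the 100-iteration resampled cal/cv/val ensemble.

Partial least squares regression (via scikit-learn's NIPALS implementation,
mean-centering only, no unit-variance scaling) maps the 101-band analysis
spectra to plant population. Model complexity (number of latent components)
is chosen per resampling iteration on a cross-validation split.

Resampling topology (``per-iteration``, the default): each iteration draws
a random 25% validation hold-out; the remaining 75% pool is further split
75/25 into calibration and cross-validation sets that drive component
selection; the final model is refit on the whole pool at the selected
complexity and predicts the hold-out. Per-sample hold-out predictions are
averaged across the iterations in which the sample was held out, and
calibration / cross-validation / validation R-squared and RMSE are reported
both as per-iteration means and as the regression of the averaged
predictions on the measured values. The alternative reading -- one fixed
validation set with 100 cal/cv shuffles of the remainder -- is available as
``topology='fixed-validation'`` and is never silently mixed with the
default.

R-squared here is the squared Pearson correlation of the predicted-vs-
measured regression (the two vectors are regressed on each other), not
1 - SS_res / SS_tot; RMSE is in population units (plants x 10^4/ha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import ValidationError


class Metrics(NamedTuple):
    r_squared: float
    rmse: float


def metrics(measured: np.ndarray, predicted: np.ndarray) -> Metrics:
    """(R-squared, RMSE) of predicted vs. measured.

    R-squared is the squared Pearson correlation (NaN when either vector
    has zero variance); RMSE is sqrt(mean squared error) in the units of
    the measurement.
    """
    m = np.asarray(measured, float)
    p = np.asarray(predicted, float)
    if m.shape != p.shape or m.size < 2:
        raise ValidationError("need two equal-length vectors of size >= 2")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
        raise ValidationError("metrics inputs must be finite")
    rmse = float(np.sqrt(np.mean((p - m) ** 2)))
    if np.std(m) == 0 or np.std(p) == 0:
        return Metrics(float("nan"), rmse)
    r = np.corrcoef(m, p)[0, 1]
    return Metrics(float(r * r), rmse)


# ---------------------------------------------------------------------------
# PLS core
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """A fitted PLS1 regression model.

    ``coef`` maps centered spectra to centered response:
    yhat = (X - x_mean) @ coef + y_mean. Missing bands in prediction inputs
    are filled with the training-fold band means recorded in
    ``imputation_means``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    imputation_means: np.ndarray
    imputed_bands: np.ndarray = field(default_factory=lambda: np.array([], int))
    x_weights: Optional[np.ndarray] = None
    x_loadings: Optional[np.ndarray] = None
    y_loadings: Optional[np.ndarray] = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        one = X.ndim == 1
        X = np.atleast_2d(X)
        if np.any(~np.isfinite(X)):
            X = np.where(np.isfinite(X), X, self.imputation_means)
        yhat = (X - self.x_mean) @ self.coef + self.y_mean
        return yhat[0] if one else yhat


def _impute_columns(X: np.ndarray) -> tuple:
    """Replace NaNs with per-column means (columns all-NaN become 0)."""
    col_means = np.nanmean(
        np.where(np.isfinite(X), X, np.nan), axis=0, keepdims=True
    )
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    bad = ~np.isfinite(X)
    if bad.any():
        X = np.where(bad, np.broadcast_to(col_means, X.shape), X)
    return X, col_means.ravel(), np.nonzero(bad.any(axis=0))[0]


def _fit_sklearn_pls(X: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*y residual is constant.*"
        )
        est = PLSRegression(n_components=k, scale=False)
        est.fit(X, y)
    return est


def fit_pls(X, y, n_components: int) -> PlsModel:
    """Fit a PLS1 model with ``n_components`` latent variables.

    The requested complexity is capped at min(n_samples - 1, n_bands) with
    a warning -- beyond that the latent directions are not identifiable.
    NaN entries are mean-imputed within the training data and recorded.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    cap = min(n - 1, p)
    if n_components > cap:
        warnings.warn(
            f"n_components reduced from {n_components} to {cap}",
            stacklevel=2,
        )
        n_components = cap
    if n < n_components + 1:
        raise ValidationError("need at least n_components + 1 samples")
    X, imput_means, imputed = _impute_columns(X)
    est = _fit_sklearn_pls(X, y, n_components)
    return PlsModel(
        n_components=n_components,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        coef=np.asarray(est.coef_).reshape(p, -1)[:, 0]
        if np.asarray(est.coef_).shape[0] == p
        else np.asarray(est.coef_).ravel(),
        imputation_means=imput_means,
        imputed_bands=imputed,
        x_weights=est.x_weights_,
        x_loadings=est.x_loadings_,
        y_loadings=est.y_loadings_,
    )


def _coef_path(X: np.ndarray, y: np.ndarray, kmax: int) -> tuple:
    """Coefficient vectors for every truncation 1..kmax from one fit.

    NIPALS components are computed sequentially, so the model with k
    components is exactly the kmax-fit truncated to its first k latent
    directions: coef_k = W_k (P_k^T W_k)^{-1} Q_k^T.
    """
    est = _fit_sklearn_pls(X, y, kmax)
    W, P, Q = est.x_weights_, est.x_loadings_, est.y_loadings_
    coefs = []
    for k in range(1, kmax + 1):
        Rk = W[:, :k] @ np.linalg.pinv(P[:, :k].T @ W[:, :k])
        coefs.append((Rk @ Q[:, :k].T).ravel())
    return coefs, X.mean(axis=0), float(np.mean(y))


def select_ncomp(
    X_cal,
    y_cal,
    X_cv,
    y_cv,
    max_components: int = 15,
) -> int:
    """Smallest component count minimising cross-validation RMSE.

    Evaluates 1..max_components (capped at the identifiable limit) and
    returns the argmin; ties -- including exact-fit plateaus in noise-free
    data -- break to the smallest count (within a 1e-8 relative tolerance).
    """
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    X_cal = np.asarray(X_cal, float)
    y_cal = np.asarray(y_cal, float).ravel()
    X_cv = np.asarray(X_cv, float)
    y_cv = np.asarray(y_cv, float).ravel()
    if len(X_cal) == 0 or len(X_cv) == 0:
        raise ValidationError("calibration and cv splits must be nonempty")
    kmax = min(max_components, len(X_cal) - 1, X_cal.shape[1])
    X_cal, imput_means, _ = _impute_columns(X_cal)
    X_cv = np.where(np.isfinite(X_cv), X_cv, imput_means)
    coefs, x_mean, y_mean = _coef_path(X_cal, y_cal, kmax)
    Xc = X_cv - x_mean
    rmses = np.array(
        [np.sqrt(np.mean((Xc @ c + y_mean - y_cv) ** 2)) for c in coefs]
    )
    best = rmses.min()
    tol = 1e-8 * max(best, 1.0) + 1e-12
    return int(np.nonzero(rmses <= best + tol)[0][0]) + 1


# ---------------------------------------------------------------------------
# resampling ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Output of the resampled calibration/cross-validation/validation loop.

    ``per_sample`` has one row per input sample with its measured value,
    the mean and SD of its hold-out predictions, and how often it was held
    out. ``metrics`` holds per-iteration mean (and SD) R-squared/RMSE for
    the calibration, cross_validation and validation phases, plus
    ``validation_aggregated``: the regression of the averaged hold-out
    predictions on the measured values (the headline reporting style).
    """

    per_sample: pd.DataFrame
    metrics: dict
    n_iterations: int
    seed: int
    grouping: str = ""
    topology: str = "per-iteration"
    selected_components: Optional[np.ndarray] = None
    external: Optional[pd.DataFrame] = None


def _phase_summary(values: list) -> dict:
    arr = np.asarray(values, float)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Mean of empty.*")
        return {
            "r_squared": float(np.nanmean(arr[:, 0])),
            "rmse": float(np.nanmean(arr[:, 1])),
            "r_squared_sd": float(np.nanstd(arr[:, 0])),
            "rmse_sd": float(np.nanstd(arr[:, 1])),
        }


def run_ensemble(
    X,
    y,
    iterations: int = 100,
    holdout_fraction: float = 0.25,
    cal_fraction: float = 0.75,
    max_components: int = 15,
    topology: str = "per-iteration",
    refit_on: str = "pool",
    seed: int = 0,
    sample_ids: Optional[np.ndarray] = None,
    X_external=None,
    y_external=None,
    grouping: str = "",
) -> EnsembleResult:
    """Run the resampled PLSR ensemble (see module docstring).

    ``X_external`` / ``y_external``, when given, are predicted by every
    iteration's final model (used for cross-condition validation); their
    aggregated metrics land in ``metrics['external']`` /
    ``metrics['external_aggregated']``.

    Per-iteration randomness derives from ``(seed, iteration)`` so any
    single iteration is reproducible in isolation.
    """
    if isinstance(X, pd.DataFrame):
        sample_ids = X.index.to_numpy() if sample_ids is None else sample_ids
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n < 12:
        raise ValidationError("need at least 12 samples for the 3-way split")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if topology not in ("per-iteration", "fixed-validation"):
        raise ValidationError(f"unknown topology {topology!r}")
    if refit_on not in ("pool", "cal"):
        raise ValidationError(f"unknown refit_on {refit_on!r}")
    ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids)

    has_ext = X_external is not None
    if has_ext:
        if isinstance(X_external, pd.DataFrame):
            ext_ids = X_external.index.to_numpy()
            X_external = X_external.to_numpy(float)
        else:
            ext_ids = np.arange(len(X_external))
        X_external = np.asarray(X_external, float)
        y_external = np.asarray(y_external, float).ravel()

    n_val = max(1, round(holdout_fraction * n))
    pred_sum = np.zeros(n)
    pred_sq = np.zeros(n)
    held = np.zeros(n, dtype=int)
    ext_preds = np.zeros((iterations, len(X_external))) if has_ext else None
    phase_vals: dict = {"calibration": [], "cross_validation": [], "validation": []}
    if has_ext:
        phase_vals["external"] = []
    ncomps = np.zeros(iterations, dtype=int)

    if topology == "fixed-validation":
        rng0 = np.random.default_rng(np.random.SeedSequence((seed, 1 << 20)))
        fixed_val = rng0.permutation(n)[:n_val]
        fixed_pool = np.setdiff1d(np.arange(n), fixed_val)

    for t in range(iterations):
        rng = np.random.default_rng(np.random.SeedSequence((seed, t)))
        if topology == "per-iteration":
            perm = rng.permutation(n)
            val, pool = perm[:n_val], perm[n_val:]
        else:
            val = fixed_val
            pool = rng.permutation(fixed_pool)
        n_cv = max(1, round((1.0 - cal_fraction) * len(pool)))
        pool = rng.permutation(pool)
        cv, cal = pool[:n_cv], pool[n_cv:]

        k = select_ncomp(X[cal], y[cal], X[cv], y[cv], max_components)
        ncomps[t] = k
        sel = fit_pls(X[cal], y[cal], k)
        phase_vals["cross_validation"].append(metrics(y[cv], sel.predict(X[cv])))

        fit_idx = pool if refit_on == "pool" else cal
        final = fit_pls(X[fit_idx], y[fit_idx], min(k, len(fit_idx) - 1))
        phase_vals["calibration"].append(
            metrics(y[fit_idx], final.predict(X[fit_idx]))
        )
        val_pred = final.predict(X[val])
        phase_vals["validation"].append(metrics(y[val], val_pred))
        pred_sum[val] += val_pred
        pred_sq[val] += val_pred ** 2
        held[val] += 1
        if has_ext:
            ep = final.predict(X_external)
            ext_preds[t] = ep
            phase_vals["external"].append(metrics(y_external, ep))

    never = held == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} sample(s) never held out across "
            f"{iterations} iterations; predictions reported as missing",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pred = np.where(never, np.nan, pred_sum / np.maximum(held, 1))
        var = pred_sq / np.maximum(held, 1) - mean_pred ** 2
    sd_pred = np.sqrt(np.maximum(var, 0.0))
    per_sample = pd.DataFrame(
        {
            "plot_id": ids,
            "measured": y,
            "mean_predicted": mean_pred,
            "sd_predicted": np.where(never, np.nan, sd_pred),
            "n_times_held_out": held,
        }
    )
    out_metrics = {phase: _phase_summary(vals) for phase, vals in phase_vals.items()}
    ok = ~never
    if ok.sum() >= 2:
        agg = metrics(y[ok], mean_pred[ok])
        out_metrics["validation_aggregated"] = {
            "r_squared": agg.r_squared, "rmse": agg.rmse
        }
    external_df = None
    if has_ext:
        ext_mean = ext_preds.mean(axis=0)
        external_df = pd.DataFrame(
            {
                "plot_id": ext_ids,
                "measured": y_external,
                "mean_predicted": ext_mean,
                "sd_predicted": ext_preds.std(axis=0),
                "n_times_held_out": iterations,
            }
        )
        agg = metrics(y_external, ext_mean)
        out_metrics["external_aggregated"] = {
            "r_squared": agg.r_squared, "rmse": agg.rmse
        }
    return EnsembleResult(
        per_sample=per_sample,
        metrics=out_metrics,
        n_iterations=iterations,
        seed=seed,
        grouping=grouping,
        topology=topology,
        selected_components=ncomps,
        external=external_df,
    )


def cross_condition_validate(
    X_train,
    y_train,
    X_test,
    y_test,
    train_ids=None,
    test_ids=None,
    **ensemble_kwargs,
) -> EnsembleResult:
    """Train the ensemble on one acquisition condition, predict the other.

    The ensemble resamples cal/cv splits within ``X_train`` only; every
    iteration's final model predicts all of ``X_test``. Train and test plot
    sets must be disjoint.
    """
    if isinstance(X_train, pd.DataFrame) and train_ids is None:
        train_ids = X_train.index.to_numpy()
    if isinstance(X_test, pd.DataFrame) and test_ids is None:
        test_ids = X_test.index.to_numpy()
    if train_ids is not None and test_ids is not None:
        overlap = set(map(str, train_ids)) & set(map(str, test_ids))
        if overlap:
            raise ValidationError(
                f"train and test plots overlap: {sorted(overlap)[:5]}"
            )
    return run_ensemble(
        X_train,
        y_train,
        sample_ids=train_ids,
        X_external=X_test,
        y_external=y_test,
        **ensemble_kwargs,
    )
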