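"""Exhaustive normalized-difference spectral index (NDSI) band-pair screen.

NDSI(i, j) = (R_i - R_j) / (R_i + R_j) for two analysis bands. The screen
regresses measured plant population on NDSI for every canonical band pair
(band_i < band_j; 101 * 100 / 2 = 5050 pairs on the 400-900 / 5 nm grid)
and ranks pairs by the r-squared of that ordinary least-squares fit.
Ranking by |r| would give the identical order; r-squared is used for
comparability with the PLSR reporting. NDSI is scale-free, so the ranking
is invariant to any common rescaling of all spectra -- the same property
that makes relative reflectance illumination-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grids import analysis_grid

REFERENCE_PAIR = (565, 710)  # green / red-edge pair of special interest


@dataclass
class BandPairResult:
    band_i: int
    band_j: int
    r_squared: float
    slope: float
    intercept: float
    rmse: float
    rank: int
    n_used: int = 0
    degenerate: bool = False


def _band_index(wavelengths: np.ndarray, band: float) -> int:
    idx = np.nonzero(wavelengths == band)[0]
    if len(idx) == 0:
        raise ValidationError(f"band {band} nm is not on the analysis grid")
    return int(idx[0])


def ndsi_value(
    values: np.ndarray,
    band_i: float,
    band_j: float,
    wavelengths: Optional[np.ndarray] = None,
    eps: float = 1e-6,
) -> float:
    """NDSI of one spectrum at a band pair; NaN if R_i + R_j <= eps."""
    wl = analysis_grid() if wavelengths is None else np.asarray(wavelengths)
    if band_i == band_j:
        raise ValidationError("band_i and band_j must differ")
    i, j = _band_index(wl, band_i), _band_index(wl, band_j)
    v = np.asarray(values, float)
    denom = v[..., i] + v[..., j]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) <= eps, np.nan, (v[..., i] - v[..., j]) / denom)
    return out if out.ndim else float(out)


def ndsi_matrix(
    X: np.ndarray, pairs: Tuple[np.ndarray, np.ndarray], eps: float = 1e-6
) -> np.ndarray:
    """NDSI for every (row, pair): X is n x bands, pairs are index arrays."""
    Xi, Xj = X[:, pairs[0]], X[:, pairs[1]]
    denom = Xi + Xj
    with np.errstate(invalid="ignore", divide="ignore"):
        N = (Xi - Xj) / denom
    N[np.abs(denom) <= eps] = np.nan
    return N


def scan_all_pairs(
    X,
    populations: np.ndarray,
    wavelengths: Optional[np.ndarray] = None,
    eps: float = 1e-6,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """OLS screen of population on NDSI over all canonical band pairs.

    Returns a DataFrame with columns band_i, band_j, r_squared, slope,
    intercept, rmse, n_used, degenerate, rank -- sorted by r_squared
    descending with ties broken by (band_i, band_j); ranks are dense
    (1..n_pairs). Pairs with zero NDSI variance get r_squared 0 and the
    ``degenerate`` flag; pairs missing on more than ``max_missing_frac`` of
    plots are excluded from ranking (rank = 0, flag ``dropped``).
    """
    if isinstance(X, pd.DataFrame):
        wavelengths = X.columns.to_numpy(float) if wavelengths is None else wavelengths
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(populations, float)
    wl = analysis_grid() if wavelengths is None else np.asarray(wavelengths)
    n, p = X.shape
    if n < 3:
        raise ValidationError("need at least 3 plots for the band-pair screen")
    if len(y) != n or not np.all(np.isfinite(y)):
        raise ValidationError("populations must be finite, one per plot")

    ii, jj = np.triu_indices(p, k=1)
    N = ndsi_matrix(X, (ii, jj), eps)  # n x n_pairs
    valid = np.isfinite(N)
    n_used = valid.sum(axis=0)
    dropped = n_used < (1.0 - max_missing_frac) * n

    Nm = np.ma.masked_invalid(N)
    ybc = np.ma.masked_array(np.broadcast_to(y[:, None], N.shape), mask=Nm.mask)
    x_mean = Nm.mean(axis=0)
    y_mean = ybc.mean(axis=0)
    dx = Nm - x_mean
    dy = ybc - y_mean
    sxx = (dx * dx).sum(axis=0)
    syy = (dy * dy).sum(axis=0)
    sxy = (dx * dy).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.ma.filled(sxy / sxx, np.nan)
        r2 = np.ma.filled((sxy * sxy) / (sxx * syy), np.nan)
    degenerate = ~np.isfinite(r2) | (np.ma.filled(sxx, 0.0) <= 0)
    r2 = np.where(degenerate, 0.0, r2)
    slope = np.where(degenerate, 0.0, slope)
    intercept = np.ma.filled(y_mean, np.nan) - slope * np.ma.filled(x_mean, np.nan)
    # residual mean square of the OLS fit, in population units
    with np.errstate(invalid="ignore"):
        ss_res = np.ma.filled(syy, np.nan) * (1.0 - r2)
    rmse = np.sqrt(np.maximum(ss_res, 0.0) / np.maximum(n_used, 1))

    df = pd.DataFrame(
        {
            "band_i": wl[ii].astype(int),
            "band_j": wl[jj].astype(int),
            "r_squared": r2,
            "slope": slope,
            "intercept": intercept,
            "rmse": rmse,
            "n_used": n_used,
            "degenerate": degenerate,
            "dropped": dropped,
        }
    )
    ranked = df[~df.dropped].sort_values(
        ["r_squared", "band_i", "band_j"], ascending=[False, True, True]
    )
    df["rank"] = 0
    df.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
    return df.sort_values(
        ["rank"], key=lambda s: s.where(s > 0, np.inf)
    ).reset_index(drop=True)


def pair_rank(scan: pd.DataFrame, pair: Tuple[int, int]) -> Optional[int]:
    """Dense rank of a canonical band pair in a scan result (None if absent)."""
    i, j = min(pair), max(pair)
    row = scan[(scan.band_i == i) & (scan.band_j == j)]
    if row.empty or int(row["rank"].iloc[0]) == 0:
        return None
    return int(row["rank"].iloc[0])


def top_pair_frequency(
    scans: Sequence[pd.DataFrame], pair: Tuple[int, int] = REFERENCE_PAIR,
    k: int = 10
) -> Tuple[int, list]:
    """Count datasets whose scan places ``pair`` within the top ``k``.

    Returns ``(count, per_dataset_ranks)``; ranks are None where the pair
    was dropped.
    """
    if not scans:
        raise ValidationError("no scan results supplied")
    ranks = [pair_rank(scan, pair) for scan in scans]
    count = sum(1 for r in ranks if r is not None and r <= k)
    return count, ranks


@dataclass
class NdsiModel:
    """Univariate linear population model on a single NDSI feature."""

    band_i: int
    band_j: int
    slope: float
    intercept: float
    eps: float = 1e-6

    def predict(self, X, wavelengths: Optional[np.ndarray] = None) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            wavelengths = X.columns.to_numpy(float)
            X = X.to_numpy(float)
        nd = ndsi_value(X, self.band_i, self.band_j, wavelengths, self.eps)
        return self.intercept + self.slope * np.asarray(nd, float)


def fit_ndsi_model(
    X_train,
    y_train: np.ndarray,
    pair: Tuple[int, int],
    wavelengths: Optional[np.ndarray] = None,
    eps: float = 1e-6,
) -> NdsiModel:
    """OLS fit of population on NDSI at one band pair."""
    if isinstance(X_train, pd.DataFrame):
        wavelengths = X_train.columns.to_numpy(float)
        X_train = X_train.to_numpy(float)
    i, j = min(pair), max(pair)
    nd = np.asarray(
        ndsi_value(X_train, i, j, wavelengths, eps), float
    )
    y = np.asarray(y_train, float)
    ok = np.isfinite(nd)
    if ok.sum() < 3:
        raise ValidationError("too few finite NDSI values to fit")
    slope, intercept = np.polyfit(nd[ok], y[ok], 1)
    return NdsiModel(i, j, float(slope), float(intercept), eps)


def permutation_max_r2(
    X,
    populations: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    eps: float = 1e-6,
) -> np.ndarray:
    """Null distribution of the scan's maximum r-squared by permutation.

    Shuffles the population vector and recomputes, for each shuffle, the
    maximum squared correlation between population and any pair's NDSI --
    the honest reference for judging an observed scan maximum against the
    multiplicity of 5050 correlated screens.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(populations, float)
    n, p = X.shape
    ii, jj = np.triu_indices(p, k=1)
    N = ndsi_matrix(X, (ii, jj), eps)
    ok = np.all(np.isfinite(N), axis=0)
    Z = N[:, ok] - N[:, ok].mean(axis=0)
    Z /= np.maximum(np.sqrt((Z * Z).sum(axis=0)), 1e-300)
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        yc /= np.sqrt((yc * yc).sum())
        out[b] = np.max((yc @ Z) ** 2)
    return out
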