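"""Reflectance spectra -> smoothed 5 nm analysis spectra and plot means.

Committed processing order (a regression test pins it): interpolate the
native ~1.33 nm grid to 1 nm, Savitzky-Golay smooth (2nd-order polynomial,
5-point window -- 5 nm on the 1 nm grid), then aggregate to 5 nm block
means over 400-900 nm and average per plot. Smoothing before aggregation
matters: swapping the two changes the result.

Nothing in this module reads the sky-condition label; processing is
condition-agnostic by construction.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import EmptyPlotError, ValidationError
from .grids import (
    ANALYSIS_N,
    ANALYSIS_START,
    ANALYSIS_STOP,
    analysis_grid,
)
from .types import AnalysisSpectrum, ReflectanceSpectrum


def to_1nm(wavelengths: np.ndarray, values: np.ndarray) -> tuple:
    """Linearly interpolate a spectrum onto integer-nm wavelengths.

    The output grid spans every integer nm inside the native span; no
    extrapolation beyond the native endpoints. NaNs in the input propagate
    to the integer bands whose interpolation interval touches them.
    """
    wl = np.asarray(wavelengths, dtype=float)
    v = np.asarray(values, dtype=float)
    if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
        raise ValidationError("native grid must be strictly increasing")
    grid = np.arange(int(np.ceil(wl[0])), int(np.floor(wl[-1])) + 1)
    return grid, np.interp(grid, wl, v)


def savgol(values: np.ndarray, window: int = 5, order: int = 2,
           axis: int = -1) -> np.ndarray:
    """Savitzky-Golay smoothing (default: 5-point window, 2nd order).

    Standard least-squares polynomial convolution; edges are handled by a
    polynomial fit on the truncated window (scipy's ``mode='interp'``).
    Polynomials up to ``order`` pass through unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd and >= 3")
    if order >= window:
        raise ValidationError("order must be < window")
    return savgol_filter(np.asarray(values, float), window, order,
                         axis=axis, mode="interp")


def to_5nm(grid_1nm: np.ndarray, values: np.ndarray) -> tuple:
    """Aggregate a 1 nm spectrum to 5 nm block means over 400-900 nm.

    Each output band at wavelength L is the mean of input bands
    L-2 ... L+2; everything outside 400-900 nm is trimmed. NaN input bands
    are dropped from their window mean and the affected output band flagged
    ``partial`` (NaN only if the whole window is missing).

    Returns ``(analysis_wavelengths, values, partial_flags)``.
    """
    grid = np.asarray(grid_1nm)
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != grid.shape[0]:
        raise ValidationError("values and grid must have equal length")
    lo, hi = ANALYSIS_START - 2, ANALYSIS_STOP + 2
    if grid[0] > lo or grid[-1] < hi:
        raise ValidationError(
            f"1 nm grid must cover {lo}-{hi} nm, got {grid[0]}-{grid[-1]}"
        )
    if not np.array_equal(np.diff(grid), np.ones(len(grid) - 1)):
        raise ValidationError("expected a contiguous integer 1 nm grid")
    i0 = int(lo - grid[0])
    block = v[..., i0 : i0 + ANALYSIS_N * 5].reshape(v.shape[:-1] + (ANALYSIS_N, 5))
    n_valid = np.sum(np.isfinite(block), axis=-1)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(block, axis=-1)
    partial = (n_valid > 0) & (n_valid < 5)
    return analysis_grid(), out, partial


def sequence_to_analysis(spectrum: ReflectanceSpectrum) -> AnalysisSpectrum:
    """Full per-sequence chain: 1 nm interpolation -> smoothing -> 5 nm."""
    grid1, v1 = to_1nm(spectrum.wavelengths, spectrum.values)
    smoothed = savgol(v1)
    wl5, v5, partial = to_5nm(grid1, smoothed)
    return AnalysisSpectrum(
        wavelengths=wl5,
        values=v5,
        plot_id=spectrum.plot_id,
        n_sequences_averaged=1,
        condition=spectrum.condition,
        band_flags={"partial": partial},
    )


def plot_mean(spectra: Sequence[AnalysisSpectrum],
              plot_id: Optional[str] = None) -> AnalysisSpectrum:
    """Bandwise arithmetic mean of the QC-passing spectra of one plot.

    Sequences from both passes (the two center rows) are pooled into a
    single plot mean.
    """
    spectra = list(spectra)
    if not spectra:
        raise EmptyPlotError(f"no QC-passing spectra for plot {plot_id!r}")
    pid = plot_id or spectra[0].plot_id
    if any(s.plot_id != spectra[0].plot_id for s in spectra):
        raise ValidationError("plot_mean received spectra from multiple plots")
    stack = np.vstack([s.values for s in spectra])
    first = spectra[0]
    return AnalysisSpectrum(
        wavelengths=first.wavelengths,
        values=stack.mean(axis=0),
        plot_id=pid,
        n_sequences_averaged=len(spectra),
        condition=first.condition,
        stage=first.stage,
        replicate=first.replicate,
    )


def process_plot(
    reflectance_spectra: Iterable[ReflectanceSpectrum],
    plot_id: Optional[str] = None,
) -> AnalysisSpectrum:
    """Per-sequence smoothing/aggregation followed by the plot mean."""
    per_seq = [sequence_to_analysis(s) for s in reflectance_spectra]
    return plot_mean(per_seq, plot_id=plot_id)


def spectra_to_matrix(spectra: Sequence[AnalysisSpectrum]) -> pd.DataFrame:
    """Stack plot-mean spectra into a wide (plots x 101 bands) DataFrame."""
    if not spectra:
        raise ValidationError("no spectra to stack")
    wl = spectra[0].wavelengths.astype(int)
    data = np.vstack([s.values for s in spectra])
    return pd.DataFrame(data, index=[s.plot_id for s in spectra], columns=wl)


def assign_plots(
    positions: np.ndarray,
    centroids: pd.DataFrame,
    max_distance_m: float = 0.15,
) -> List[Optional[str]]:
    """Nearest-centroid plot assignment for coordinate-bearing inputs.

    ``centroids`` must have columns ``plot_id``, ``x``, ``y``. Points
    farther than ``max_distance_m`` from every centroid (the upper end of
    typical differential-GPS accuracy) are returned as None. Plot labels in
    the standard tables are trusted as-is; this helper exists only for raw
    coordinate streams.
    """
    pts = np.atleast_2d(np.asarray(positions, float))
    cxy = centroids[["x", "y"]].to_numpy(float)
    ids = centroids["plot_id"].tolist()
    out: List[Optional[str]] = []
    for p in pts:
        d = np.hypot(*(cxy - p).T)
        j = int(np.argmin(d))
        out.append(ids[j] if d[j] <= max_distance_m else None)
    return out
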