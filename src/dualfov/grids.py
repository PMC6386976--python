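"""Wavelength grids used throughout the pipeline.

The spectrometer covers 340-1022 nm with a 1.33 nm full-width-half-maximum
optical resolution; we idealise the native sampling as an exactly uniform
1.33 nm grid (513 points, 340.00-1020.96 nm). Downstream analysis happens on
the 1 nm interpolated grid and finally on the 400-900 nm / 5 nm analysis
grid (101 bands).
"""

from __future__ import annotations

import numpy as np

NATIVE_START_NM = 340.0
NATIVE_STEP_NM = 1.33
NATIVE_N = 513

ONE_NM_START = 340
ONE_NM_STOP = 1020  # last integer nm inside the native span (no extrapolation)

ANALYSIS_START = 400
ANALYSIS_STOP = 900
ANALYSIS_STEP = 5
ANALYSIS_N = 101


def native_grid() -> np.ndarray:
    """Native spectrometer wavelength grid in nm (513 uniform samples)."""
    return NATIVE_START_NM + NATIVE_STEP_NM * np.arange(NATIVE_N)


def one_nm_grid() -> np.ndarray:
    """Integer-nm grid covered by the native grid without extrapolation."""
    return np.arange(ONE_NM_START, ONE_NM_STOP + 1)


def analysis_grid() -> np.ndarray:
    """400-900 nm analysis grid at 5 nm spacing (101 bands)."""
    return np.arange(ANALYSIS_START, ANALYSIS_STOP + 1, ANALYSIS_STEP)
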