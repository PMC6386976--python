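"""Core data containers shared across the pipeline.

These are deliberately thin: arrays plus provenance. Heavy lifting lives in
the functional modules (radiometry, preprocessing, ndsi, chemometrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SequenceIncompleteError, ValidationError

FRAME_NAMES = ("up_dark", "up_target", "down_target", "down_dark")


@dataclass
class RawFrame:
    """One spectrometer readout.

    Parameters
    ----------
    channel : {'up', 'down'}
        Fiber channel: 'up' views the target (upwelling radiance), 'down'
        views the sky through the cosine fore-optic (downwelling irradiance).
    is_dark : bool
        True for a closed-shutter dark-current frame.
    integration_time_ms : float
        Detector integration time in milliseconds (> 0).
    wavelengths : ndarray
        Native wavelength grid in nm.
    counts : ndarray
        Raw detector counts, same length as ``wavelengths``. Stored as
        floats; simulated noise-free frames carry non-integer expectations.
    saturated : bool
        True if any count hit the detector full well.
    """

    channel: str
    is_dark: bool
    integration_time_ms: float
    wavelengths: np.ndarray
    counts: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.channel not in ("up", "down"):
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.integration_time_ms <= 0:
            raise ValidationError("integration_time_ms must be > 0")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.wavelengths.shape:
            raise ValidationError("counts and wavelengths must have equal length")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")


@dataclass
class MeasurementSequence:
    """The four-frame unit yielding one relative-reflectance sample.

    Frames follow the acquisition order: upwelling dark, upwelling target,
    downwelling target, downwelling dark. Darks are per-sequence and are
    never shared across sequences.
    """

    sequence_id: str
    plot_id: str
    frames: dict
    row_index: int = 1
    condition: Optional[str] = None
    position: Optional[tuple] = None

    def __post_init__(self) -> None:
        missing = [name for name in FRAME_NAMES if name not in self.frames]
        if missing:
            raise SequenceIncompleteError(
                f"sequence {self.sequence_id}: missing frames {missing}"
            )

    def frame(self, name: str) -> RawFrame:
        try:
            return self.frames[name]
        except KeyError:
            raise SequenceIncompleteError(
                f"sequence {self.sequence_id}: missing frame {name}"
            ) from None

    @property
    def any_saturated(self) -> bool:
        return any(f.saturated for f in self.frames.values())


@dataclass
class ReflectanceSpectrum:
    """Relative reflectance on the native grid, with per-band QC flags.

    ``band_flags`` maps flag name -> boolean array (True = flagged band).
    ``flags`` is the set of flag names raised on at least one band, plus any
    sequence-level flags.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sequence_id: str = ""
    plot_id: str = ""
    condition: Optional[str] = None
    flags: set = field(default_factory=set)
    band_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValidationError("values and wavelengths must have equal length")


@dataclass
class AnalysisSpectrum:
    """Reflectance on the 400-900 nm / 5 nm analysis grid (101 bands)."""

    wavelengths: np.ndarray
    values: np.ndarray
    plot_id: str = ""
    n_sequences_averaged: int = 1
    condition: Optional[str] = None
    stage: Optional[str] = None
    replicate: Optional[int] = None
    band_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.wavelengths) != 101:
            raise ValidationError("analysis grid must have exactly 101 bands")
        if self.values.shape != self.wavelengths.shape:
            raise ValidationError("values and wavelengths must have equal length")
        if self.n_sequences_averaged < 1:
            raise ValidationError("n_sequences_averaged must be >= 1")
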