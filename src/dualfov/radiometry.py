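"""Raw four-frame sequences -> relative reflectance.

The instrument measures upwelling radiance and downwelling irradiance with
one detector through two fibers of different diameter, at different
integration times. Relative reflectance normalises both channels for dark
current, integration time, and fiber throughput and takes their ratio:

    R(lambda) = K * [(C_up - C_up,dark) / (t_up * g_up)]
                  / [(C_down - C_down,dark) / (t_down * g_down)]

with g proportional to fiber cross-sectional area (diameter squared) and K
a single dimensionless system constant. Because any change of illumination
multiplies both channels equally, R is invariant under joint rescaling --
the property that makes measurements comparable across sunny and overcast
skies without a white reference.

K defaults to 1.0: "relative" reflectance only needs internal consistency,
not absolute calibration. Any unquantified field-of-view geometry factor
(cosine fore-optic vs. bare fiber) is folded into K and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import (
    DegenerateSequenceError,
    PairingError,
    ValidationError,
)
from .types import MeasurementSequence, RawFrame, ReflectanceSpectrum

EDGE_LO_NM = 400.0
EDGE_HI_NM = 900.0


@dataclass
class ThroughputModel:
    """Fiber throughput and system-constant model.

    The effective throughput ratio g_down / g_up equals
    (d_down / d_up)^2 unless ``throughput_ratio_override`` is given.
    """

    fiber_diameter_up_um: float = 400.0
    fiber_diameter_down_um: float = 600.0
    throughput_ratio_override: Optional[float] = None
    k_constant: float = 1.0

    def __post_init__(self) -> None:
        if min(self.fiber_diameter_up_um, self.fiber_diameter_down_um) <= 0:
            raise ValidationError("fiber diameters must be > 0")
        if self.throughput_ratio_override is not None and (
            self.throughput_ratio_override <= 0
        ):
            raise ValidationError("throughput ratio override must be > 0")

    @property
    def throughput_up(self) -> float:
        return (self.fiber_diameter_up_um / 400.0) ** 2

    @property
    def throughput_down(self) -> float:
        if self.throughput_ratio_override is not None:
            return self.throughput_up * self.throughput_ratio_override
        return (self.fiber_diameter_down_um / 400.0) ** 2


def dark_subtract(
    target: RawFrame, dark: RawFrame, dark_sd: Optional[float] = None
) -> tuple:
    """Subtract a dark frame from its paired target frame.

    Frames must share channel, wavelength grid, and integration time
    (exactly). Negative net counts are preserved -- clamping would bias
    low-signal bands -- but flagged where they fall below -3 * dark_sd
    (estimated from the dark frame when not supplied).

    Returns ``(net_counts, negative_flags)``.
    """
    if target.is_dark or not dark.is_dark:
        raise PairingError("expected a (target, dark) frame pair")
    if target.channel != dark.channel:
        raise PairingError(
            f"channel mismatch: {target.channel!r} vs {dark.channel!r}"
        )
    if not np.array_equal(target.wavelengths, dark.wavelengths):
        raise PairingError("wavelength grid mismatch between target and dark")
    if target.integration_time_ms != dark.integration_time_ms:
        raise PairingError("integration time mismatch between target and dark")
    net = target.counts - dark.counts
    sd = float(np.std(dark.counts)) if dark_sd is None else float(dark_sd)
    flags = net < -3.0 * sd if sd > 0 else net < 0.0
    return net, flags


def relative_reflectance(
    seq: MeasurementSequence,
    tm: Optional[ThroughputModel] = None,
    min_irradiance: float = 1.0,
    dark_sd: Optional[float] = None,
) -> ReflectanceSpectrum:
    """Compute relative reflectance for one four-frame sequence.

    Bands whose dark-subtracted downwelling signal is at or below
    ``min_irradiance`` counts are set to NaN and flagged
    ``low_irradiance``; bands outside 400-900 nm are flagged ``edge`` (they
    sit on noisy detector edges and are trimmed by preprocessing). Raises
    if any frame is saturated (precondition: QC excludes those upstream) or
    if every band fails the irradiance floor.
    """
    tm = tm or ThroughputModel()
    if seq.any_saturated:
        raise ValidationError(
            f"sequence {seq.sequence_id}: saturated frame; run QC first"
        )
    up_t, up_d = seq.frame("up_target"), seq.frame("up_dark")
    dn_t, dn_d = seq.frame("down_target"), seq.frame("down_dark")
    up_net, up_neg = dark_subtract(up_t, up_d, dark_sd)
    dn_net, dn_neg = dark_subtract(dn_t, dn_d, dark_sd)

    up_norm = up_net / (up_t.integration_time_ms * tm.throughput_up)
    dn_norm = dn_net / (dn_t.integration_time_ms * tm.throughput_down)

    low = dn_net <= min_irradiance
    if np.all(low):
        raise DegenerateSequenceError(
            f"sequence {seq.sequence_id}: no band passes the irradiance floor"
        )
    values = np.full_like(up_norm, np.nan)
    ok = ~low
    values[ok] = tm.k_constant * up_norm[ok] / dn_norm[ok]

    wl = up_t.wavelengths
    band_flags = {
        "edge": (wl < EDGE_LO_NM) | (wl > EDGE_HI_NM),
        "low_irradiance": low,
        "negative_net_up": up_neg,
        "negative_net_down": dn_neg,
    }
    flags = {name for name, mask in band_flags.items() if np.any(mask)}
    return ReflectanceSpectrum(
        wavelengths=wl,
        values=values,
        sequence_id=seq.sequence_id,
        plot_id=seq.plot_id,
        condition=seq.condition,
        flags=flags,
        band_flags=band_flags,
    )


@dataclass
class QcLimits:
    """Acceptance limits for sequence-level quality control."""

    it_up_range_ms: tuple = (13.0, 15.0)
    it_down_range_ms: tuple = (4.0, 6.0)
    max_negative_irradiance_frac: float = 0.10
    median_r_ceiling: float = 2.0


@dataclass
class QcResult:
    passed: bool
    flags: set = field(default_factory=set)


def sequence_qc(
    seq: MeasurementSequence,
    limits: Optional[QcLimits] = None,
    tm: Optional[ThroughputModel] = None,
) -> QcResult:
    """Deterministic pass/fail screen for one sequence.

    Fails on any saturated frame, on negative net downwelling signal over
    more than the configured fraction of bands, on integration times
    outside the configured ranges, or on an implausibly high median
    reflectance (e.g. the operator error of recording the upwelling frame
    on both channels).
    """
    limits = limits or QcLimits()
    tm = tm or ThroughputModel()
    flags = set()
    if seq.any_saturated:
        flags.add("saturated")
    tol = 1e-9
    t_up = seq.frame("up_target").integration_time_ms
    t_dn = seq.frame("down_target").integration_time_ms
    lo, hi = limits.it_up_range_ms
    if not (lo - tol <= t_up <= hi + tol):
        flags.add("integration_time_out_of_range")
    lo, hi = limits.it_down_range_ms
    if not (lo - tol <= t_dn <= hi + tol):
        flags.add("integration_time_out_of_range")

    if "saturated" not in flags:
        dn_net, _ = dark_subtract(seq.frame("down_target"), seq.frame("down_dark"))
        if np.mean(dn_net < 0) > limits.max_negative_irradiance_frac:
            flags.add("negative_irradiance")
        else:
            try:
                spec = relative_reflectance(seq, tm)
            except DegenerateSequenceError:
                flags.add("degenerate")
            else:
                finite = np.isfinite(spec.values) & ~spec.band_flags["edge"]
                if np.any(finite) and (
                    np.median(spec.values[finite]) > limits.median_r_ceiling
                ):
                    flags.add("implausible_ratio")
    return QcResult(passed=not flags, flags=flags)


def process_sequences(
    sequences: Iterable[MeasurementSequence],
    tm: Optional[ThroughputModel] = None,
    limits: Optional[QcLimits] = None,
    min_irradiance: float = 1.0,
) -> tuple:
    """QC-screen and convert a batch of sequences to reflectance spectra.

    Returns ``(spectra, rejected)`` where ``rejected`` lists
    ``(sequence_id, flags)`` for sequences that failed QC.
    """
    tm = tm or ThroughputModel()
    spectra, rejected = [], []
    for seq in sequences:
        qc = sequence_qc(seq, limits, tm)
        if not qc.passed:
            rejected.append((seq.sequence_id, qc.flags))
            continue
        spectra.append(relative_reflectance(seq, tm, min_irradiance))
    return spectra, rejected
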