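"""Synthetic dual field-of-view trial generator.

Emulates a tractor-mounted dual-FOV spectrometer (one detector, two fibers:
a 400 um bare fiber viewing the canopy and a 600 um fiber viewing the sky
through a cosine fore-optic) measuring soybean plots at early vegetative
stages under sunny or overcast skies. The generator produces raw four-frame
count sequences plus plot metadata with the statistical structure the
downstream analysis assumes:

* downwelling irradiance with a solar-like spectral shape; cloudy skies have
  a much lower, per-sequence variable magnitude but (by default) the same
  spectral shape, so true reflectance is illumination-invariant;
* canopy reflectance as a linear soil/vegetation mixture whose vegetation
  fraction saturates with plant population (foliage overlap at later
  stages);
* dark current, Poisson shot noise, and detector saturation on a uniform
  340-1022 nm / 1.33 nm native grid;
* the full trial design: 2 replicates x 4 stages x 2 row spacings x
  2 tillages x 2 cultivars x 14 seeding rates (3.7-51.8 plants x 10^4/ha),
  26 sequences per plot (13 samples per row, two center rows).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .grids import native_grid
from .types import MeasurementSequence, RawFrame

STAGES = ("VC", "V1", "V2", "V3")
CONDITIONS = ("sunny", "cloudy")

#: Reference fiber diameter (um) against which throughput areas are scaled.
_D_REF_UM = 400.0


# ---------------------------------------------------------------------------
# acquisition geometry
# ---------------------------------------------------------------------------

def footprint_radius(height_m: float = 0.60, view_angle_deg: float = 25.0) -> float:
    """Ground-level footprint radius of the bare upwelling fiber.

    A fiber with full view angle ``view_angle_deg`` held ``height_m`` above
    the canopy sees a disc of radius h * tan(angle / 2). The default
    geometry (0.60 m, 25 deg) gives ~0.13 m.
    """
    if height_m <= 0 or not (0 < view_angle_deg < 180):
        raise ValidationError("height must be > 0 and view angle in (0, 180)")
    return height_m * math.tan(math.radians(view_angle_deg / 2.0))


def samples_per_row(
    row_length_m: float = 7.6,
    speed_m_s: float = 0.22,
    sample_interval_s: float = 2.6,
) -> int:
    """Number of spectral samples collected along one plot row.

    The tractor traverses ``row_length_m`` at ``speed_m_s`` while one
    four-frame sequence starts every ``sample_interval_s``; the count is the
    floor of traversal time over cadence (13 for the default geometry).
    """
    if min(row_length_m, speed_m_s, sample_interval_s) <= 0:
        raise ValidationError("geometry parameters must be positive")
    return int(math.floor((row_length_m / speed_m_s) / sample_interval_s))


# ---------------------------------------------------------------------------
# illumination
# ---------------------------------------------------------------------------

def solar_irradiance(
    wavelengths: Optional[np.ndarray] = None,
    temperature_k: float = 5800.0,
    peak: float = 2500.0,
) -> np.ndarray:
    """Smooth solar-like downwelling irradiance shape (relative units).

    A Planck curve at the solar effective temperature, normalised so its
    maximum over the native grid equals ``peak``. Units are arbitrary
    "counts per ms per unit fiber area": with the default sensor the sunny
    downwelling channel then peaks near 30k counts at a 5 ms integration.
    """
    wl = native_grid() if wavelengths is None else np.asarray(wavelengths, float)
    # Planck spectral radiance vs wavelength; hc/k = 1.4388e7 nm K.
    x = 1.4388e7 / (wl * temperature_k)
    b = wl ** -5.0 / np.expm1(x)
    return peak * b / b.max()


def nir_shape_perturbation(
    amplitude: float, wavelengths: Optional[np.ndarray] = None
) -> np.ndarray:
    """Smooth multiplicative up-weighting of bands beyond ~750 nm.

    Used to emulate a mild near-infrared divergence between sky conditions;
    applied to the downwelling channel only, so it leaks into retrieved
    reflectance (the intended imperfection). Off by default.
    """
    wl = native_grid() if wavelengths is None else np.asarray(wavelengths, float)
    return amplitude / (1.0 + np.exp(-(wl - 775.0) / 15.0))


@dataclass
class IlluminationModel:
    """Downwelling illumination for one sky condition.

    ``magnitude_scale`` is the nominal brightness relative to clear sky;
    ``scale_range``, when set, draws the per-sequence brightness uniformly
    (emulating scattered-to-full cloud). ``temporal_jitter_sd`` adds
    per-sequence multiplicative log-normal jitter shared by both channels,
    so it cancels in the reflectance ratio. ``shape_perturbation`` is a
    multiplicative spectral factor (1 + s) applied to the *downwelling*
    channel only.
    """

    condition: str
    magnitude_scale: float = 1.0
    base_irradiance: Optional[np.ndarray] = None
    scale_range: Optional[tuple] = None
    shape_perturbation: Optional[np.ndarray] = None
    temporal_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.magnitude_scale <= 0:
            raise ValidationError("magnitude_scale must be > 0")
        if self.temporal_jitter_sd < 0:
            raise ValidationError("temporal_jitter_sd must be >= 0")
        if self.base_irradiance is not None:
            self.base_irradiance = np.asarray(self.base_irradiance, float)
            if np.any(self.base_irradiance < 0):
                raise ValidationError("base_irradiance must be nonnegative")
        if self.scale_range is not None:
            lo, hi = self.scale_range
            if not (0 < lo <= hi):
                raise ValidationError("scale_range must satisfy 0 < lo <= hi")

    def irradiance(self, wavelengths: Optional[np.ndarray] = None) -> np.ndarray:
        if self.base_irradiance is not None:
            return self.base_irradiance
        return solar_irradiance(wavelengths)

    def draw_scale(self, rng: np.random.Generator) -> float:
        if self.scale_range is None:
            return self.magnitude_scale
        return float(rng.uniform(*self.scale_range))


def illumination_for(
    condition: str,
    nir_divergence: float = 0.0,
    deterministic: bool = False,
) -> IlluminationModel:
    """Default illumination model for a sky condition.

    Sunny: full brightness, <= 1% temporal jitter. Cloudy: nominal 0.3 of
    clear-sky brightness, drawn per sequence from [0.1, 0.5], 5% jitter.
    ``nir_divergence`` > 0 turns on the NIR shape perturbation for cloudy
    skies (amplitude as a fraction, e.g. 0.03 for 3%). ``deterministic``
    freezes the brightness at its nominal value and removes jitter.
    """
    pert = None
    if condition == "sunny":
        model = IlluminationModel(
            "sunny", magnitude_scale=1.0, temporal_jitter_sd=0.01
        )
    elif condition == "cloudy":
        if nir_divergence > 0:
            pert = nir_shape_perturbation(nir_divergence)
        model = IlluminationModel(
            "cloudy",
            magnitude_scale=0.3,
            scale_range=(0.1, 0.5),
            shape_perturbation=pert,
            temporal_jitter_sd=0.05,
        )
    else:
        raise ValidationError(f"unknown condition {condition!r}")
    if deterministic:
        model = replace(model, scale_range=None, temporal_jitter_sd=0.0)
    return model


# ---------------------------------------------------------------------------
# canopy
# ---------------------------------------------------------------------------

def make_vegetation_endmember(
    red_edge_nm: float = 715.0,
    nir_plateau: float = 0.45,
    green_peak: float = 0.12,
    red_level: float = 0.04,
    red_edge_width_nm: float = 10.0,
    wavelengths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Parametric green-vegetation reflectance spectrum on the native grid.

    Gaussian green peak near 550 nm over a low red-absorption baseline,
    plus a logistic red edge rising to the NIR plateau. Values stay in
    [0, 1] and the curve is smooth (no jumps between adjacent bands).
    """
    for name, v in (("nir_plateau", nir_plateau), ("green_peak", green_peak),
                    ("red_level", red_level)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    if not 680.0 <= red_edge_nm <= 760.0:
        raise ValidationError("red_edge_nm must be within 680-760 nm")
    if red_edge_width_nm <= 0:
        raise ValidationError("red_edge_width_nm must be > 0")
    wl = native_grid() if wavelengths is None else np.asarray(wavelengths, float)
    base = red_level + (green_peak - red_level) * np.exp(
        -((wl - 550.0) ** 2) / (2.0 * 30.0 ** 2)
    )
    edge = (nir_plateau - red_level) / (
        1.0 + np.exp(-(wl - red_edge_nm) / red_edge_width_nm)
    )
    return np.clip(base + edge, 0.0, 1.0)


def make_soil_endmember(
    level_340: float = 0.10,
    level_1022: float = 0.28,
    wavelengths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Bare-soil reflectance: a gentle linear ramp rising with wavelength."""
    if not (0 <= level_340 <= 1 and 0 <= level_1022 <= 1):
        raise ValidationError("soil levels must be in [0, 1]")
    wl = native_grid() if wavelengths is None else np.asarray(wavelengths, float)
    t = (wl - 340.0) / (1022.0 - 340.0)
    return level_340 + (level_1022 - level_340) * t


@dataclass
class CanopyModel:
    """Soil/vegetation mixture model with population-dependent cover.

    ``cover_coefficient`` maps development stage to the effective canopy
    area per plant (in units of (plants x 10^4/ha)^-1, i.e. per plant/m^2),
    increasing with stage as seedlings grow. Fractional cover follows
    f = 1 - exp(-(c * population)^overlap_exponent): linear at low density,
    saturating as foliage overlaps.

    Heterogeneity parameters (all optional realism, not part of the cover
    law): ``stage_sampling_cv`` is the per-sequence multiplicative spread of
    cover inside the small fiber footprint (large for small V1 seedlings
    that are often missed by the footprint, small for V3); ``plot_cover_sd``
    is per-plot establishment patchiness; ``soil_brightness_sd`` and
    ``tillage_soil_factor`` vary the soil background per plot and tillage;
    ``row_spacing_exponent`` boosts cover for narrow rows, which spread the
    same population more evenly.
    """

    veg_endmember: np.ndarray = field(default_factory=make_vegetation_endmember)
    soil_endmember: np.ndarray = field(default_factory=make_soil_endmember)
    cover_coefficient: dict = field(
        default_factory=lambda: {"VC": 0.008, "V1": 0.012, "V2": 0.020, "V3": 0.030}
    )
    overlap_exponent: float = 1.0
    stage_sampling_cv: dict = field(
        default_factory=lambda: {"VC": 0.90, "V1": 0.75, "V2": 0.35, "V3": 0.18}
    )
    plot_cover_sd: float = 0.03
    soil_brightness_sd: float = 0.05
    tillage_soil_factor: dict = field(
        default_factory=lambda: {"NT": 1.0, "CT": 1.15}
    )
    row_spacing_exponent: float = 0.25

    def __post_init__(self) -> None:
        self.veg_endmember = np.asarray(self.veg_endmember, float)
        self.soil_endmember = np.asarray(self.soil_endmember, float)
        for name, em in (("veg", self.veg_endmember), ("soil", self.soil_endmember)):
            if np.any(em < 0) or np.any(em > 1):
                raise ValidationError(f"{name} endmember must lie in [0, 1]")
        if self.overlap_exponent <= 0:
            raise ValidationError("overlap_exponent must be > 0")
        if any(c < 0 for c in self.cover_coefficient.values()):
            raise ValidationError("cover coefficients must be >= 0")


def fractional_cover(
    population: float, stage: str, canopy: CanopyModel
) -> float:
    """Fraction of the footprint covered by vegetation at a given density.

    f = 1 - exp(-(c_stage * population)^k): zero at zero population,
    monotone nondecreasing, concave for k = 1, asymptoting to full cover as
    foliage overlaps. ``population`` is in plants x 10^4 per hectare
    (equivalently plants per m^2).
    """
    if population < 0:
        raise ValidationError("population must be >= 0")
    if stage not in canopy.cover_coefficient:
        raise ValidationError(f"unknown stage {stage!r}")
    c = canopy.cover_coefficient[stage]
    return float(-np.expm1(-((c * population) ** canopy.overlap_exponent)))


def canopy_reflectance(
    cover: float,
    canopy: CanopyModel,
    soil: Optional[np.ndarray] = None,
    veg: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Linear mixture R = f * veg + (1 - f) * soil, bandwise."""
    if not 0.0 <= cover <= 1.0:
        raise ValidationError("cover must be in [0, 1]")
    veg = canopy.veg_endmember if veg is None else veg
    soil = canopy.soil_endmember if soil is None else soil
    return cover * veg + (1.0 - cover) * soil


# ---------------------------------------------------------------------------
# sensor
# ---------------------------------------------------------------------------

@dataclass
class SensorModel:
    """Detector and fiber model for the dual-FOV instrument.

    Fiber throughput scales with cross-sectional area, i.e. diameter
    squared; counts are expected signal + dark level, with optional Poisson
    shot noise and Gaussian read noise of ``dark_sd`` counts. Integration
    times are drawn uniformly per sequence from the per-channel ranges
    (upwelling 13-15 ms, downwelling 4-6 ms by default).
    """

    fiber_diameter_up_um: float = 400.0
    fiber_diameter_down_um: float = 600.0
    it_up_range_ms: tuple = (13.0, 15.0)
    it_down_range_ms: tuple = (4.0, 6.0)
    dark_level: float = 180.0
    dark_sd: float = 4.0
    full_well: float = 65535.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if min(self.fiber_diameter_up_um, self.fiber_diameter_down_um) <= 0:
            raise ValidationError("fiber diameters must be > 0")
        for lo, hi in (self.it_up_range_ms, self.it_down_range_ms):
            if not (0 < lo <= hi):
                raise ValidationError("integration-time ranges must be positive")
        if not 0 <= self.dark_level < self.full_well:
            raise ValidationError("dark_level must satisfy 0 <= dark < full_well")
        if self.dark_sd < 0:
            raise ValidationError("dark_sd must be >= 0")

    @property
    def throughput_up(self) -> float:
        return (self.fiber_diameter_up_um / _D_REF_UM) ** 2

    @property
    def throughput_down(self) -> float:
        return (self.fiber_diameter_down_um / _D_REF_UM) ** 2

    @classmethod
    def noise_free(cls, **kw) -> "SensorModel":
        """Sensor with shot and read noise disabled (for exact round trips)."""
        kw.setdefault("shot_noise", False)
        kw.setdefault("dark_sd", 0.0)
        return cls(**kw)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _frame_counts(
    expected: np.ndarray, sensor: SensorModel, rng: np.random.Generator
) -> np.ndarray:
    counts = np.asarray(expected, dtype=float)
    if sensor.shot_noise:
        counts = rng.poisson(counts).astype(float)
    if sensor.dark_sd > 0:
        counts = counts + rng.normal(0.0, sensor.dark_sd, size=counts.shape)
    return np.maximum(counts, 0.0)


def simulate_sequence(
    reflectance: np.ndarray,
    illum: IlluminationModel,
    sensor: SensorModel,
    rng_seed,
    sequence_id: str = "seq",
    plot_id: str = "",
    row_index: int = 1,
) -> MeasurementSequence:
    """Simulate one four-frame measurement of a target reflectance.

    Expected dark-subtracted upwelling counts are proportional to
    reflectance x irradiance x t_up x fiber-area(up); downwelling counts to
    irradiance x t_down x fiber-area(down). Illumination brightness and
    temporal jitter are shared by both channels and therefore cancel in the
    reflectance ratio; a downwelling-only ``shape_perturbation`` does not.

    If the expected peak would saturate, the offending channel's
    integration time is redrawn once from the lower half of its range; if
    still saturating, counts are clipped and the frame flagged.

    ``rng_seed`` may be an integer or a ``numpy.random.Generator``;
    identical seeds give identical frames.
    """
    wl = native_grid()
    refl = np.asarray(reflectance, dtype=float)
    if refl.shape != wl.shape:
        raise ValidationError("reflectance must be on the native grid")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    base = illum.irradiance(wl)
    if not np.any(base > 0):
        raise DegenerateInputError("illumination is zero everywhere")
    scale = illum.draw_scale(rng)
    jitter = (
        math.exp(rng.normal(0.0, illum.temporal_jitter_sd))
        if illum.temporal_jitter_sd > 0
        else 1.0
    )
    irr = base * scale * jitter
    irr_down = irr * (1.0 + illum.shape_perturbation) \
        if illum.shape_perturbation is not None else irr

    t_up = float(rng.uniform(*sensor.it_up_range_ms))
    t_down = float(rng.uniform(*sensor.it_down_range_ms))

    def expected(signal_per_ms_area, t, g):
        return sensor.dark_level + signal_per_ms_area * t * g

    # one saturation-avoiding redraw per channel, then clip + flag
    up_signal = refl * irr
    down_signal = irr_down
    for _ in range(1):
        if expected(up_signal, t_up, sensor.throughput_up).max() > sensor.full_well:
            lo, hi = sensor.it_up_range_ms
            t_up = float(rng.uniform(lo, (lo + hi) / 2.0))
        if expected(down_signal, t_down, sensor.throughput_down).max() > sensor.full_well:
            lo, hi = sensor.it_down_range_ms
            t_down = float(rng.uniform(lo, (lo + hi) / 2.0))

    frames = {}
    specs = {
        "up_dark": ("up", True, t_up, np.full_like(wl, sensor.dark_level)),
        "up_target": ("up", False, t_up,
                      expected(up_signal, t_up, sensor.throughput_up)),
        "down_target": ("down", False, t_down,
                        expected(down_signal, t_down, sensor.throughput_down)),
        "down_dark": ("down", True, t_down, np.full_like(wl, sensor.dark_level)),
    }
    for name, (channel, is_dark, t, exp_counts) in specs.items():
        counts = _frame_counts(exp_counts, sensor, rng)
        saturated = bool(np.any(counts > sensor.full_well))
        if saturated:
            counts = np.minimum(counts, sensor.full_well)
        frames[name] = RawFrame(
            channel=channel,
            is_dark=is_dark,
            integration_time_ms=t,
            wavelengths=wl,
            counts=counts,
            saturated=saturated,
        )
    return MeasurementSequence(
        sequence_id=sequence_id,
        plot_id=plot_id,
        frames=frames,
        row_index=row_index,
        condition=illum.condition,
    )


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

def default_condition_schedule(
    replicates: int = 2, stages: tuple = STAGES
) -> dict:
    """Sky-condition schedule mirroring the canonical trial calendar.

    Replicate 1 was measured under sun at V1, replicate 2 at V3; every
    other (replicate, stage) combination was overcast.
    """
    schedule = {}
    for rep in range(1, replicates + 1):
        for stage in stages:
            sunny = (rep == 1 and stage == "V1") or (rep == 2 and stage == "V3")
            schedule[(rep, stage)] = "sunny" if sunny else "cloudy"
    return schedule


@dataclass
class TrialDesign:
    """Factorial field-trial layout and acquisition plan.

    Defaults reproduce the canonical design: 2 replicates x 4 vegetative
    stages x 2 row spacings (0.38 / 0.76 m) x 2 tillages (no-till /
    conventional) x 2 cultivars x 14 seeding rates spanning 3.7-51.8
    plants x 10^4/ha, with 13 samples per row over 2 center rows per plot.
    Measured population = seeding rate x a per-plot emergence draw.
    """

    replicates: int = 2
    stages: tuple = STAGES
    row_spacings: tuple = (0.38, 0.76)
    tillages: tuple = ("NT", "CT")
    cultivars: tuple = ("C1", "C2")
    seeding_rates: tuple = tuple(np.round(3.7 * np.arange(1, 15), 1))
    emergence_mean: float = 0.85
    emergence_sd: float = 0.08
    samples_per_row: int = 13
    rows_per_plot: int = 2
    condition_schedule: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.asarray(self.seeding_rates, float)
        if len(rates) < 1 or np.any(np.diff(rates) <= 0):
            raise ValidationError("seeding rates must be strictly increasing")
        if not 0 < self.emergence_mean <= 1:
            raise ValidationError("emergence_mean must be in (0, 1]")
        if self.emergence_sd < 0:
            raise ValidationError("emergence_sd must be >= 0")
        if self.samples_per_row < 1 or self.rows_per_plot < 1:
            raise ValidationError("sampling plan must be >= 1 per dimension")
        if self.condition_schedule is None:
            self.condition_schedule = default_condition_schedule(
                self.replicates, tuple(self.stages)
            )
        for rep in range(1, self.replicates + 1):
            for stage in self.stages:
                if (rep, stage) not in self.condition_schedule:
                    raise ValidationError(
                        f"condition_schedule missing ({rep}, {stage})"
                    )

    @property
    def sequences_per_plot(self) -> int:
        return self.samples_per_row * self.rows_per_plot


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

class Trial:
    """A generated trial: plot metadata plus lazily simulated sequences.

    ``plots`` holds one record per (replicate, stage, row spacing, tillage,
    cultivar, seeding rate) combination with measured population, sky
    condition, and the ground-truth vegetation cover used to render its
    spectra. Sequences are simulated on demand so the full design never has
    to sit in memory; every draw is keyed by (design seed, record, sequence
    index), making generation order-independent and deterministic.
    """

    def __init__(
        self,
        design: TrialDesign,
        canopy: CanopyModel,
        sensor: SensorModel,
        illum_by_condition: dict,
    ):
        self.design = design
        self.canopy = canopy
        self.sensor = sensor
        self.illum_by_condition = dict(illum_by_condition)
        for cond in {c for (_, c) in design.condition_schedule.items()}:
            if cond not in self.illum_by_condition:
                raise ValidationError(f"no illumination model for {cond!r}")
        self.plots = self._build_plots()

    # -- plot table ---------------------------------------------------------
    def _build_plots(self) -> pd.DataFrame:
        d = self.design
        records = []
        phys = list(
            itertools.product(
                range(1, d.replicates + 1),
                d.row_spacings,
                d.tillages,
                d.cultivars,
                d.seeding_rates,
            )
        )
        for phys_idx, (rep, rs, till, cv, rate) in enumerate(phys):
            rng = np.random.default_rng(
                np.random.SeedSequence((d.seed, 0, phys_idx))
            )
            emergence = float(
                np.clip(rng.normal(d.emergence_mean, d.emergence_sd), 0.05, 1.0)
            )
            population = rate * emergence
            soil_factor = self.canopy.tillage_soil_factor.get(till, 1.0) * (
                1.0 + rng.normal(0.0, self.canopy.soil_brightness_sd)
            )
            soil_factor = max(soil_factor, 0.05)
            plot_id = f"R{rep}_{rs:.2f}_{till}_{cv}_{rate:g}"
            for stage_idx, stage in enumerate(d.stages):
                rec_rng = np.random.default_rng(
                    np.random.SeedSequence((d.seed, 1, phys_idx, stage_idx))
                )
                c_eff = self.canopy.cover_coefficient[stage] * (
                    0.76 / rs
                ) ** self.canopy.row_spacing_exponent
                f = -np.expm1(
                    -((c_eff * population) ** self.canopy.overlap_exponent)
                )
                f_plot = float(
                    np.clip(
                        f * (1.0 + rec_rng.normal(0.0, self.canopy.plot_cover_sd)),
                        0.0,
                        1.0,
                    )
                )
                records.append(
                    {
                        "record_id": f"{plot_id}:{stage}",
                        "plot_id": plot_id,
                        "replicate": rep,
                        "stage": stage,
                        "row_spacing": rs,
                        "tillage": till,
                        "cultivar": cv,
                        "seeding_rate": rate,
                        "emergence": emergence,
                        "measured_population": population,
                        "condition": d.condition_schedule[(rep, stage)],
                        "true_cover": f_plot,
                        "soil_factor": soil_factor,
                        "phys_index": phys_idx,
                        "stage_index": stage_idx,
                    }
                )
        return pd.DataFrame.from_records(records)

    # -- sequences ----------------------------------------------------------
    def sequences_for(self, record) -> list:
        """Simulate the 26 (or configured) sequences for one plot record."""
        d = self.design
        canopy = self.canopy
        cv_stage = canopy.stage_sampling_cv.get(record["stage"], 0.0)
        soil = np.clip(canopy.soil_endmember * record["soil_factor"], 0.0, 1.0)
        illum = self.illum_by_condition[record["condition"]]
        sequences = []
        n = d.sequences_per_plot
        for seq_idx in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    (d.seed, 2, int(record["phys_index"]),
                     int(record["stage_index"]), seq_idx)
                )
            )
            if cv_stage > 0:
                jitter = math.exp(
                    rng.normal(0.0, cv_stage) - cv_stage ** 2 / 2.0
                )
            else:
                jitter = 1.0
            cover = float(np.clip(record["true_cover"] * jitter, 0.0, 1.0))
            refl = canopy_reflectance(cover, canopy, soil=soil)
            row = 1 + seq_idx // d.samples_per_row
            seq = simulate_sequence(
                refl,
                illum,
                self.sensor,
                rng,
                sequence_id=f"{record['record_id']}:{seq_idx:02d}",
                plot_id=record["record_id"],
                row_index=row,
            )
            sequences.append(seq)
        return sequences

    def iter_sequences(self) -> Iterator[MeasurementSequence]:
        for _, record in self.plots.iterrows():
            yield from self.sequences_for(record)

    # -- materialised tables -------------------------------------------------
    def to_frames(self) -> tuple:
        """Materialise (sequence long table, plot table) as DataFrames.

        The long table has one row per (sequence, frame, wavelength); only
        use this for small designs -- the full canonical trial is ~48M rows.
        """
        rows = []
        for seq in self.iter_sequences():
            for frame_name, frame in seq.frames.items():
                n = len(frame.wavelengths)
                rows.append(
                    pd.DataFrame(
                        {
                            "sequence_id": np.repeat(seq.sequence_id, n),
                            "plot_id": np.repeat(seq.plot_id, n),
                            "row_index": np.repeat(seq.row_index, n),
                            "frame": np.repeat(frame_name, n),
                            "integration_time_ms": np.repeat(
                                frame.integration_time_ms, n
                            ),
                            "wavelength_nm": frame.wavelengths,
                            "counts": frame.counts,
                        }
                    )
                )
        seq_table = pd.concat(rows, ignore_index=True)
        plot_cols = [
            "record_id", "plot_id", "replicate", "stage", "row_spacing",
            "tillage", "cultivar", "seeding_rate", "measured_population",
            "condition", "true_cover",
        ]
        return seq_table, self.plots[plot_cols].copy()


def generate_trial(
    design: Optional[TrialDesign] = None,
    canopy: Optional[CanopyModel] = None,
    sensor: Optional[SensorModel] = None,
    illum_by_condition: Optional[dict] = None,
    nir_divergence: float = 0.0,
) -> Trial:
    """Generate a synthetic trial under the given (or default) models."""
    design = design or TrialDesign()
    canopy = canopy or CanopyModel()
    sensor = sensor or SensorModel()
    if illum_by_condition is None:
        illum_by_condition = {
            c: illumination_for(c, nir_divergence=nir_divergence)
            for c in CONDITIONS
        }
    return Trial(design, canopy, sensor, illum_by_condition)
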