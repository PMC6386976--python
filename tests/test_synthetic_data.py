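"""Generator: endmembers, cover law, sequence simulation, trial layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dualfov.errors import DegenerateInputError, ValidationError
from dualfov.grids import native_grid
from dualfov.radiometry import relative_reflectance
from dualfov.synthetic_data import (
    CanopyModel,
    IlluminationModel,
    SensorModel,
    TrialDesign,
    canopy_reflectance,
    fractional_cover,
    generate_trial,
    illumination_for,
    make_soil_endmember,
    make_vegetation_endmember,
    simulate_sequence,
)

from conftest import make_tiny_design


class TestVegetationEndmember:
    def test_spectral_ordering_and_smoothness(self):
        wl = native_grid()
        v = make_vegetation_endmember()
        at = lambda nm: v[np.argmin(np.abs(wl - nm))]
        assert at(670) < at(550) < at(800)
        assert np.all(v >= 0) and np.all(v <= 1)
        assert np.max(np.abs(np.diff(v))) < 0.05

    def test_red_edge_inflection_position(self):
        # steepest rise of the default spectrum sits in the red-edge region
        wl = native_grid()
        v = make_vegetation_endmember()
        infl = wl[np.argmax(np.diff(v))]
        assert 700 <= infl <= 730

    def test_all_dark_degenerate_spectrum(self):
        v = make_vegetation_endmember(nir_plateau=0.0, green_peak=0.0,
                                      red_level=0.0)
        assert np.allclose(v, 0.0)

    @pytest.mark.parametrize(
        "kw", [dict(red_edge_nm=600.0), dict(nir_plateau=1.5),
               dict(green_peak=-0.1), dict(red_edge_width_nm=0.0)]
    )
    def test_parameter_validation(self, kw):
        with pytest.raises(ValidationError):
            make_vegetation_endmember(**kw)


class TestFractionalCover:
    def test_zero_population_zero_cover(self):
        assert fractional_cover(0.0, "V3", CanopyModel()) == 0.0

    def test_closed_form(self):
        # default V3 coefficient is 0.03: f(30) = 1 - e^-0.9
        canopy = CanopyModel()
        expected = 1.0 - np.exp(-0.9)
        assert fractional_cover(30.0, "V3", canopy) == pytest.approx(
            expected, abs=1e-12
        )

    @given(st.floats(0.0, 60.0), st.floats(0.0, 60.0))
    def test_monotone_in_population(self, p1, p2):
        canopy = CanopyModel()
        lo, hi = sorted((p1, p2))
        assert fractional_cover(lo, "V2", canopy) <= fractional_cover(
            hi, "V2", canopy
        )

    @given(st.floats(0.0, 60.0))
    def test_later_stage_covers_more(self, p):
        canopy = CanopyModel()
        assert fractional_cover(p, "V3", canopy) >= fractional_cover(
            p, "V1", canopy
        )

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            fractional_cover(-1.0, "V1", CanopyModel())


class TestCanopyReflectance:
    def test_mixture_endpoints_and_midpoint(self):
        canopy = CanopyModel()
        assert np.array_equal(canopy_reflectance(0.0, canopy),
                              canopy.soil_endmember)
        assert np.array_equal(canopy_reflectance(1.0, canopy),
                              canopy.veg_endmember)
        mid = canopy_reflectance(0.5, canopy)
        assert np.allclose(
            mid, 0.5 * (canopy.veg_endmember + canopy.soil_endmember)
        )

    @given(st.floats(0.0, 1.0))
    def test_within_endmember_hull(self, cover):
        canopy = CanopyModel()
        r = canopy_reflectance(cover, canopy)
        lo = np.minimum(canopy.veg_endmember, canopy.soil_endmember)
        hi = np.maximum(canopy.veg_endmember, canopy.soil_endmember)
        assert np.all(r >= lo - 1e-12) and np.all(r <= hi + 1e-12)


class TestSimulateSequence:
    def test_noise_free_round_trip(self):
        refl = make_vegetation_endmember()
        seq = simulate_sequence(
            refl, illumination_for("sunny", deterministic=True),
            SensorModel.noise_free(), 11,
        )
        rec = relative_reflectance(seq).values
        assert np.nanmax(np.abs(rec - refl) / refl) < 1e-10

    @given(st.floats(0.05, 20.0))
    def test_illumination_invariance(self, scale):
        # recovered reflectance does not depend on illumination magnitude
        refl = canopy_reflectance(0.4, CanopyModel())
        sensor = SensorModel.noise_free(full_well=1e12)
        ref = relative_reflectance(
            simulate_sequence(
                refl, illumination_for("sunny", deterministic=True), sensor, 5
            )
        ).values
        dim = IlluminationModel("cloudy", magnitude_scale=scale)
        other = relative_reflectance(
            simulate_sequence(refl, dim, sensor, 5)
        ).values
        assert np.nanmax(np.abs(ref - other)) < 1e-10

    def test_count_scale_ratio_and_identical_reflectance(self):
        # 5x brighter sky -> 5x net counts on every band, same reflectance
        refl = canopy_reflectance(0.5, CanopyModel())
        sensor = SensorModel.noise_free()
        bright = IlluminationModel("sunny", magnitude_scale=1.0)
        dim = IlluminationModel("cloudy", magnitude_scale=0.2)
        s1 = simulate_sequence(refl, bright, sensor, 42)
        s2 = simulate_sequence(refl, dim, sensor, 42)
        for frame in ("up_target", "down_target"):
            net1 = s1.frames[frame].counts - sensor.dark_level
            net2 = s2.frames[frame].counts - sensor.dark_level
            assert np.allclose(net1, 5.0 * net2, rtol=1e-12)
        r1 = relative_reflectance(s1).values
        r2 = relative_reflectance(s2).values
        assert np.nanmax(np.abs(r1 - r2)) < 1e-10

    def test_shot_noise_recovery_is_unbiased(self):
        # Monte Carlo: the per-band mean of 200 noisy retrievals matches the
        # truth within its standard error (>= 93% of bands within 2 SE,
        # allowing binomial fluctuation of the nominal 95% coverage over
        # 513 bands; no band beyond 5 SE).
        refl = canopy_reflectance(0.4, CanopyModel())
        illum = illumination_for("sunny", deterministic=True)
        sensor = SensorModel()
        recs = np.vstack(
            [
                relative_reflectance(
                    simulate_sequence(refl, illum, sensor, 1000 + i)
                ).values
                for i in range(200)
            ]
        )
        mean = recs.mean(axis=0)
        se = recs.std(axis=0, ddof=1) / np.sqrt(len(recs))
        z = np.abs(mean - refl) / se
        assert np.mean(z <= 2.0) >= 0.93
        assert z.max() <= 5.0

    def test_determinism(self):
        refl = canopy_reflectance(0.3, CanopyModel())
        illum = illumination_for("cloudy")
        a = simulate_sequence(refl, illum, SensorModel(), 7)
        b = simulate_sequence(refl, illum, SensorModel(), 7)
        for name in a.frames:
            assert np.array_equal(a.frames[name].counts, b.frames[name].counts)
            assert a.frames[name].integration_time_ms == (
                b.frames[name].integration_time_ms
            )

    def test_saturation_flagged(self):
        refl = make_vegetation_endmember()
        sensor = SensorModel.noise_free(full_well=1000.0)
        seq = simulate_sequence(
            refl, illumination_for("sunny", deterministic=True), sensor, 3
        )
        assert seq.any_saturated
        for f in seq.frames.values():
            assert np.all(f.counts <= sensor.full_well)

    def test_zero_irradiance_rejected(self):
        refl = make_vegetation_endmember()
        illum = IlluminationModel(
            "sunny", base_irradiance=np.zeros(len(native_grid()))
        )
        with pytest.raises(DegenerateInputError):
            simulate_sequence(refl, illum, SensorModel(), 0)


class TestTrialDesign:
    def test_canonical_plot_counts(self):
        trial = generate_trial()
        plots = trial.plots
        assert len(plots) == 896
        assert (plots.groupby("stage").size() == 224).all()
        assert plots["record_id"].is_unique

    def test_emergence_identity(self):
        design = TrialDesign(emergence_mean=1.0, emergence_sd=0.0)
        plots = generate_trial(design=design).plots
        assert np.allclose(plots["measured_population"], plots["seeding_rate"])

    def test_condition_schedule_default(self):
        plots = generate_trial().plots
        sunny = plots[plots.condition == "sunny"]
        assert set(zip(sunny.replicate, sunny.stage)) == {(1, "V1"), (2, "V3")}

    def test_seeding_rates_must_increase(self):
        with pytest.raises(ValidationError):
            TrialDesign(seeding_rates=(10.0, 5.0))

    def test_same_seed_byte_identical_tables(self, tiny_design):
        t1 = generate_trial(design=tiny_design)
        t2 = generate_trial(design=make_tiny_design())
        s1, p1 = t1.to_frames()
        s2, p2 = t2.to_frames()
        assert s1.to_csv(index=False) == s2.to_csv(index=False)
        assert p1.to_csv(index=False) == p2.to_csv(index=False)

    def test_sequences_per_plot(self, tiny_design):
        trial = generate_trial(design=tiny_design)
        record = trial.plots.iloc[0]
        seqs = trial.sequences_for(record)
        assert len(seqs) == tiny_design.sequences_per_plot
        assert {s.row_index for s in seqs} <= {1, 2}


def test_nir_cover_monotonicity(quiet_canopy):
    """With noise off, plot-mean NIR reflectance rises with population."""
    from dualfov.experiment import process_trial

    design = make_tiny_design(
        seeding_rates=tuple(np.linspace(4.0, 50.0, 8)),
        stages=("V3",),
        emergence_sd=0.0,
    )
    trial = generate_trial(
        design=design,
        canopy=quiet_canopy,
        sensor=SensorModel.noise_free(),
        illum_by_condition={
            c: illumination_for(c, deterministic=True)
            for c in ("sunny", "cloudy")
        },
    )
    X = process_trial(trial)
    plots = trial.plots.set_index("record_id").loc[X.index]
    nir = X.loc[:, 760:900].mean(axis=1).to_numpy()
    order = np.argsort(plots["measured_population"].to_numpy())
    assert np.all(np.diff(nir[order]) >= -1e-12)
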