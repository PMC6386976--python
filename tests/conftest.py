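import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dualfov.chemometrics import run_ensemble
from dualfov.experiment import StudyConfig, build_dataset
from dualfov.synthetic_data import (
    CanopyModel,
    SensorModel,
    TrialDesign,
    generate_trial,
)

settings.register_profile(
    "det",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_tiny_design(**overrides) -> TrialDesign:
    """A minimal but structurally complete trial design for fast tests."""
    kw = dict(
        replicates=1,
        stages=("V1", "V3"),
        row_spacings=(0.76,),
        tillages=("NT",),
        cultivars=("C1",),
        seeding_rates=(5.0, 15.0, 30.0),
        samples_per_row=2,
        rows_per_plot=1,
        seed=3,
    )
    kw.update(overrides)
    return TrialDesign(**kw)


@pytest.fixture
def tiny_design():
    return make_tiny_design()


@pytest.fixture
def quiet_canopy():
    """Canopy without any stochastic heterogeneity (pure cover law)."""
    return CanopyModel(
        stage_sampling_cv={s: 0.0 for s in ("VC", "V1", "V2", "V3")},
        plot_cover_sd=0.0,
        soil_brightness_sd=0.0,
        tillage_soil_factor={"NT": 1.0, "CT": 1.0},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Plot-mean analysis spectra for the full default trial (seeded).

    Session-scoped: generating and processing the 896-plot trial takes a
    while, and several end-to-end checks share it.
    """
    cfg = StudyConfig(seed=1)
    X, plots = build_dataset(cfg)
    return X, plots


def make_small_study_config():
    """A reduced study: full structure, small sampling plan and ensemble."""
    from dualfov.experiment import StudyConfig

    return StudyConfig(
        seed=5,
        iterations=8,
        design=dict(
            stages=("V1", "V3"),
            seeding_rates=tuple(np.round(3.7 * np.arange(1, 8), 1)),
            samples_per_row=2,
            rows_per_plot=1,
        ),
        residual_permutations=199,
    )


@pytest.fixture(scope="session")
def small_study_reports():
    """The same small study executed twice from identical configs."""
    from dualfov.experiment import run_study

    first = run_study(make_small_study_config())
    second = run_study(make_small_study_config())
    return first, second


@pytest.fixture(scope="session")
def stage_ensembles(default_dataset):
    """100-iteration validation ensembles for each development stage."""
    X, plots = default_dataset
    out = {}
    for stage in ("VC", "V1", "V2", "V3"):
        idx = np.nonzero((plots["stage"] == stage).to_numpy())[0]
        y = plots["measured_population"].to_numpy()[idx]
        out[stage] = run_ensemble(X.iloc[idx], y, iterations=100, seed=1)
    return out
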