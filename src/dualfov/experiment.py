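"""Study orchestration: grouping, ensembles, NDSI screens, reports.

Reproduces the study layout over any dataset in the standard tables (real
or synthetic): datasets are formed at three canonical granularities --
treatment level ({stage, row spacing, tillage, replicate}: 32 groups on the
canonical design, cultivars pooled), development-stage level (4 groups,
treatments and replicates pooled) and all-data-together (1 group). Each
group gets a resampled PLSR ensemble, an exhaustive NDSI scan with the
top-k pairs, and a univariate model on the green/red-edge reference pair
(565, 710). Stages measured under opposite sky conditions in the two
replicates are additionally cross-validated sunny->cloudy and
cloudy->sunny.

Only ``cross_condition_validate`` and ``residual_condition_check`` ever
read the sky-condition label; the estimation path itself is condition-
blind.

The residual condition check (a permutation test on the difference of mean
residuals between conditions) is an addition of this package: it formalises
the visual "no trends in residuals" inspection as a reportable statistic.
It reports only -- there is no pass/fail gate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .chemometrics import cross_condition_validate, run_ensemble
from .errors import GroupingError, ValidationError
from .ndsi import REFERENCE_PAIR, ndsi_value, pair_rank, scan_all_pairs
from .preprocessing import process_plot
from .radiometry import QcLimits, ThroughputModel, process_sequences
from .synthetic_data import (
    CanopyModel,
    SensorModel,
    Trial,
    TrialDesign,
    generate_trial,
)

CANONICAL_FACTORS = {
    "treatment": ("stage", "row_spacing", "tillage", "replicate"),
    "stage": ("stage",),
    "pooled": (),
}

_VALID_FACTORS = {"stage", "row_spacing", "tillage", "cultivar", "replicate"}


@dataclass
class GroupingSpec:
    """A dataset partition over plot-table factors.

    The canonical specs are ``treatment`` (32 groups on the default
    design; replicate is the fourth factor and cultivars are pooled --
    an alternative factorisation using cultivar instead of replicate also
    reaches 32 and can be requested explicitly), ``stage`` (4) and
    ``pooled`` (1).
    """

    name: str
    factors: tuple

    def __post_init__(self) -> None:
        unknown = set(self.factors) - _VALID_FACTORS
        if unknown:
            raise GroupingError(f"unknown grouping factors: {sorted(unknown)}")

    @classmethod
    def canonical(cls, name: str) -> "GroupingSpec":
        if name not in CANONICAL_FACTORS:
            raise GroupingError(f"unknown canonical grouping {name!r}")
        return cls(name=name, factors=CANONICAL_FACTORS[name])


def build_groups(plots: pd.DataFrame, spec: GroupingSpec) -> list:
    """Partition the plot table into datasets.

    Returns ``[(group_key_dict, integer_index_array), ...]`` in a
    deterministic (sorted) order. Empty groups cannot arise from a
    partition; missing factor columns raise.
    """
    missing = [f for f in spec.factors if f not in plots.columns]
    if missing:
        raise GroupingError(f"plot table lacks grouping columns: {missing}")
    if not len(plots):
        raise GroupingError("empty plot table")
    if not spec.factors:
        return [({}, np.arange(len(plots)))]
    keys = plots[list(spec.factors)].apply(tuple, axis=1)
    groups = []
    for key in sorted(keys.unique(), key=str):
        idx = np.nonzero((keys == key).to_numpy())[0]
        groups.append((dict(zip(spec.factors, key)), idx))
    return groups


def residual_condition_check(
    per_sample: pd.DataFrame,
    conditions: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation test for a sky-condition trend in ensemble residuals.

    Residual = mean hold-out prediction minus measured value. Reports the
    cloudy-minus-sunny difference of mean residuals and a two-sided
    permutation p-value over ``n_permutations`` seeded shuffles of the
    condition labels. Informational only.
    """
    df = per_sample.dropna(subset=["mean_predicted"])
    cond = conditions.loc[df.index] if hasattr(conditions, "loc") else conditions
    cond = np.asarray(cond)
    resid = (df["mean_predicted"] - df["measured"]).to_numpy()
    is_cloudy = cond == "cloudy"
    is_sunny = cond == "sunny"
    if not (is_cloudy.any() and is_sunny.any()):
        return {"skipped": True, "note": "single-condition group"}
    observed = float(resid[is_cloudy].mean() - resid[is_sunny].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(is_cloudy)
        diff = resid[perm].mean() - resid[~perm].mean()
        if abs(diff) >= abs(observed) - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {
        "skipped": False,
        "mean_residual_difference": observed,
        "p_value": float(p),
        "n_cloudy": int(is_cloudy.sum()),
        "n_sunny": int(is_sunny.sum()),
        "n_permutations": n_permutations,
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Run configuration for a full synthetic study.

    Sizes default to the canonical trial; scale ``samples_per_row`` /
    ``iterations`` down for quick runs. ``nir_divergence`` > 0 makes cloudy
    illumination leak a mild NIR shape difference into reflectance
    (off by default).
    """

    seed: int = 0
    iterations: int = 100
    max_components: int = 15
    topology: str = "per-iteration"
    groupings: tuple = ("treatment", "stage", "pooled")
    ndsi_top_k: int = 10
    reference_pair: tuple = REFERENCE_PAIR
    nir_divergence: float = 0.0
    noise: bool = True
    design: dict = field(default_factory=dict)  # TrialDesign overrides
    residual_permutations: int = 999

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("groupings", "reference_pair"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "iterations": self.iterations,
            "max_components": self.max_components,
            "topology": self.topology,
            "groupings": list(self.groupings),
            "ndsi_top_k": self.ndsi_top_k,
            "reference_pair": list(self.reference_pair),
            "nir_divergence": self.nir_divergence,
            "noise": self.noise,
            "design": dict(self.design),
            "residual_permutations": self.residual_permutations,
        }


def build_dataset(config: StudyConfig) -> tuple:
    """Generate the synthetic trial and process it to the analysis matrix.

    Returns ``(X, plots)``: a plots x 101-band DataFrame of plot-mean
    analysis spectra indexed by record id, and the plot table.
    """
    design_kwargs = dict(config.design)
    design_kwargs.setdefault("seed", config.seed)
    design = TrialDesign(**design_kwargs)
    sensor = SensorModel() if config.noise else SensorModel.noise_free()
    trial = generate_trial(
        design=design, sensor=sensor, nir_divergence=config.nir_divergence
    )
    return process_trial(trial), trial.plots


def process_trial(trial: Trial) -> pd.DataFrame:
    """Raw sequences -> QC -> reflectance -> plot-mean analysis spectra."""
    tm = ThroughputModel(
        fiber_diameter_up_um=trial.sensor.fiber_diameter_up_um,
        fiber_diameter_down_um=trial.sensor.fiber_diameter_down_um,
    )
    limits = QcLimits(
        it_up_range_ms=trial.sensor.it_up_range_ms,
        it_down_range_ms=trial.sensor.it_down_range_ms,
    )
    rows, index = [], []
    for _, record in trial.plots.iterrows():
        spectra, _rejected = process_sequences(
            trial.sequences_for(record), tm, limits
        )
        mean = process_plot(spectra, plot_id=record["record_id"])
        rows.append(mean.values)
        index.append(record["record_id"])
    X = pd.DataFrame(
        np.vstack(rows), index=index,
        columns=np.arange(400, 901, 5),
    )
    return X


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

def _group_label(grouping: str, key: dict) -> str:
    if not key:
        return f"{grouping}"
    return grouping + ":" + ",".join(f"{k}={v}" for k, v in key.items())


def _analyse_group(
    X: pd.DataFrame,
    plots: pd.DataFrame,
    idx: np.ndarray,
    label: str,
    config: StudyConfig,
    group_seed: int,
) -> dict:
    Xg = X.iloc[idx]
    y = plots["measured_population"].to_numpy()[idx]
    ens = run_ensemble(
        Xg,
        y,
        iterations=config.iterations,
        max_components=config.max_components,
        topology=config.topology,
        seed=group_seed,
        grouping=label,
    )
    scan = scan_all_pairs(Xg, y)
    top = scan.head(config.ndsi_top_k)
    ref = tuple(config.reference_pair)
    nd_feature = ndsi_value(
        Xg.to_numpy(float), min(ref), max(ref),
        wavelengths=Xg.columns.to_numpy(float),
    )
    nd_ens = run_ensemble(
        pd.DataFrame(
            np.asarray(nd_feature, float).reshape(-1, 1), index=Xg.index
        ),
        y,
        iterations=config.iterations,
        max_components=1,
        topology=config.topology,
        seed=group_seed,
        grouping=f"{label}|ndsi",
    )
    plsr_rmse = ens.metrics["validation_aggregated"]["rmse"]
    ndsi_rmse = nd_ens.metrics["validation_aggregated"]["rmse"]
    result = {
        "n_plots": int(len(idx)),
        "plsr": ens.metrics,
        "ndsi_top_pairs": top[
            ["band_i", "band_j", "r_squared", "rmse", "rank"]
        ].to_dict("records"),
        "reference_pair_rank": pair_rank(scan, ref),
        "ndsi_model": nd_ens.metrics,
        "plsr_beats_ndsi": bool(plsr_rmse <= ndsi_rmse),
        "mean_selected_components": float(ens.selected_components.mean()),
    }
    conditions = plots["condition"].iloc[idx].reset_index(drop=True)
    if conditions.nunique() > 1:
        result["residual_condition_check"] = residual_condition_check(
            ens.per_sample,
            conditions,
            n_permutations=config.residual_permutations,
            seed=group_seed,
        )
    return result, ens, scan


def _cross_condition(
    X: pd.DataFrame, plots: pd.DataFrame, config: StudyConfig
) -> dict:
    """Sunny<->cloudy validation for stages split by condition across reps."""
    out = {}
    for stage in plots["stage"].unique():
        sub = plots[plots["stage"] == stage]
        conds = sub.groupby("replicate")["condition"].first()
        if conds.nunique() < 2:
            continue
        sides = {
            cond: sub[sub["condition"] == cond].index.to_numpy()
            for cond in conds.unique()
        }
        stage_out = {}
        for train_cond, test_cond in (
            ("sunny", "cloudy"), ("cloudy", "sunny")
        ):
            tr = plots.index.get_indexer(sides[train_cond])
            te = plots.index.get_indexer(sides[test_cond])
            res = cross_condition_validate(
                X.iloc[tr],
                plots["measured_population"].to_numpy()[tr],
                X.iloc[te],
                plots["measured_population"].to_numpy()[te],
                iterations=config.iterations,
                max_components=config.max_components,
                topology=config.topology,
                seed=config.seed,
                grouping=f"cross:{stage}:{train_cond}->{test_cond}",
            )
            stage_out[f"{train_cond}_to_{test_cond}"] = {
                "n_train": int(len(tr)),
                "n_test": int(len(te)),
                "r_squared": res.metrics["external_aggregated"]["r_squared"],
                "rmse": res.metrics["external_aggregated"]["rmse"],
            }
        gap = abs(
            stage_out["sunny_to_cloudy"]["r_squared"]
            - stage_out["cloudy_to_sunny"]["r_squared"]
        )
        stage_out["r_squared_gap"] = float(gap)
        out[str(stage)] = stage_out
    return out


def _sanitize(obj):
    """Make a report JSON-serialisable (NaN -> None, numpy -> python)."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_study(config: StudyConfig, out_dir: Optional[str] = None) -> dict:
    """Execute the full study and return the report dictionary.

    The report is deterministic given the config (seed included): rendering
    it with ``report_json`` twice yields byte-identical text. Per-group
    prediction CSVs and a timestamped sidecar are written only when
    ``out_dir`` is given, keeping the report itself timestamp-free.
    """
    X, plots = build_dataset(config)
    plots = plots.set_index("record_id", drop=False)
    X = X.loc[plots.index]

    report = {
        "config": config.to_dict(),
        "provenance": {
            "package_version": _pkg_version,
            "seed": config.seed,
            "plot_table_sha256": hashlib.sha256(
                plots.to_csv(index=False).encode()
            ).hexdigest(),
        },
        "groups": {},
        "summary": {},
    }
    per_sample_tables = {}
    treatment_scans = []
    counter = 0
    for grouping in config.groupings:
        spec = GroupingSpec.canonical(grouping)
        for key, idx in build_groups(plots, spec):
            label = _group_label(grouping, key)
            group_seed = (config.seed * 100003 + counter) % (2 ** 31 - 1)
            counter += 1
            try:
                result, ens, scan = _analyse_group(
                    X, plots, idx, label, config, group_seed
                )
            except Exception as exc:  # abort with group id and cause
                raise GroupingError(f"group {label!r} failed: {exc}") from exc
            report["groups"][label] = result
            per_sample_tables[label] = ens.per_sample
            if grouping == "treatment":
                treatment_scans.append(scan)

    if treatment_scans:
        ref = tuple(config.reference_pair)
        ranks = [pair_rank(s, ref) for s in treatment_scans]
        in_top = sum(
            1 for r in ranks if r is not None and r <= config.ndsi_top_k
        )
        report["summary"]["reference_pair_top_k_datasets"] = {
            "pair": list(ref),
            "k": config.ndsi_top_k,
            "count": in_top,
            "n_datasets": len(treatment_scans),
        }
    flags = [g["plsr_beats_ndsi"] for g in report["groups"].values()]
    if flags:
        report["summary"]["plsr_beats_ndsi_fraction"] = float(
            np.mean(flags)
        )
    report["cross_condition"] = _cross_condition(X, plots, config)
    report = _sanitize(report)

    if out_dir is not None:
        import datetime
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report_json(report))
        from .figures import predicted_vs_measured

        for label, table in per_sample_tables.items():
            safe = label.replace(":", "_").replace(",", "_").replace("=", "-")
            table.to_csv(out / f"predictions_{safe}.csv", index=False)
            if label.startswith("stage") or label == "pooled":
                predicted_vs_measured(
                    table, out / f"fig_{safe}.png", title=label
                )
        (out / "run_info.json").write_text(
            json.dumps(
                {"written_at": datetime.datetime.now().isoformat()}, indent=2
            )
        )
    return report


def report_json(report: dict) -> str:
    """Canonical JSON rendering of a study report (byte-stable)."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
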