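"""CSV / YAML interchange for the pipeline's standard tables.

Sequence table (long format): one row per (sequence, frame, wavelength)
with columns sequence_id, plot_id, row_index, frame, integration_time_ms,
wavelength_nm, counts. Plot table: one row per plot record with the trial
factors, measured population, condition, stage, replicate. Reflectance and
analysis-spectra tables are long (one row per band); the wide matrix is
plots x 101 bands.
"""

from __future__ import annotations

from typing import Iterable, List

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .types import MeasurementSequence, RawFrame, ReflectanceSpectrum

_FRAME_CHANNEL = {
    "up_dark": ("up", True),
    "up_target": ("up", False),
    "down_target": ("down", False),
    "down_dark": ("down", True),
}


def write_sequences_csv(sequences: Iterable[MeasurementSequence], path) -> None:
    rows = []
    for seq in sequences:
        for name, frame in seq.frames.items():
            n = len(frame.wavelengths)
            rows.append(
                pd.DataFrame(
                    {
                        "sequence_id": np.repeat(seq.sequence_id, n),
                        "plot_id": np.repeat(seq.plot_id, n),
                        "row_index": np.repeat(seq.row_index, n),
                        "frame": np.repeat(name, n),
                        "integration_time_ms": np.repeat(
                            frame.integration_time_ms, n
                        ),
                        "wavelength_nm": frame.wavelengths,
                        "counts": frame.counts,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_sequences_csv(path) -> List[MeasurementSequence]:
    df = pd.read_csv(path)
    required = {
        "sequence_id", "plot_id", "row_index", "frame",
        "integration_time_ms", "wavelength_nm", "counts",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sequence table lacks columns: {sorted(missing)}")
    sequences = []
    for seq_id, g in df.groupby("sequence_id", sort=False):
        frames = {}
        for frame_name, fg in g.groupby("frame", sort=False):
            if frame_name not in _FRAME_CHANNEL:
                raise ValidationError(f"unknown frame label {frame_name!r}")
            channel, is_dark = _FRAME_CHANNEL[frame_name]
            fg = fg.sort_values("wavelength_nm")
            frames[frame_name] = RawFrame(
                channel=channel,
                is_dark=is_dark,
                integration_time_ms=float(fg["integration_time_ms"].iloc[0]),
                wavelengths=fg["wavelength_nm"].to_numpy(float),
                counts=fg["counts"].to_numpy(float),
            )
        sequences.append(
            MeasurementSequence(
                sequence_id=str(seq_id),
                plot_id=str(g["plot_id"].iloc[0]),
                frames=frames,
                row_index=int(g["row_index"].iloc[0]),
            )
        )
    return sequences


def write_reflectance_csv(spectra: Iterable[ReflectanceSpectrum], path) -> None:
    rows = []
    for s in spectra:
        flag_str = np.full(len(s.wavelengths), "", dtype=object)
        for name, mask in s.band_flags.items():
            flag_str[mask] = np.where(
                flag_str[mask] == "", name, flag_str[mask] + ";" + name
            )
        rows.append(
            pd.DataFrame(
                {
                    "sequence_id": np.repeat(s.sequence_id, len(s.wavelengths)),
                    "plot_id": np.repeat(s.plot_id, len(s.wavelengths)),
                    "wavelength_nm": s.wavelengths,
                    "reflectance": s.values,
                    "flags": flag_str,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_reflectance_csv(path) -> List[ReflectanceSpectrum]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for seq_id, g in df.groupby("sequence_id", sort=False):
        g = g.sort_values("wavelength_nm")
        flags_col = g["flags"].fillna("").astype(str) if "flags" in g else None
        band_flags = {}
        if flags_col is not None:
            names = {n for cell in flags_col for n in cell.split(";") if n}
            for name in names:
                band_flags[name] = flags_col.str.split(";").apply(
                    lambda parts: name in parts
                ).to_numpy()
        out.append(
            ReflectanceSpectrum(
                wavelengths=g["wavelength_nm"].to_numpy(float),
                values=g["reflectance"].to_numpy(float),
                sequence_id=str(seq_id),
                plot_id=str(g["plot_id"].iloc[0]),
                flags={n for n, m in band_flags.items() if m.any()},
                band_flags=band_flags,
            )
        )
    return out


def write_matrix_csv(X: pd.DataFrame, path) -> None:
    X.to_csv(path, index_label="plot_id")


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="plot_id")
    df.columns = df.columns.astype(int)
    return df


def load_config(path) -> dict:
    """Load a JSON/YAML run configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg
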