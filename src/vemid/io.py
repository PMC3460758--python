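"""CSV input/output for waveforms and Monte-Carlo corpora.

Waveform files are plain UTF-8 CSV with the header
``time_s,flow_ml_s,paw_cmh2o`` and one row per sample ('.' decimal
separator).  The reader validates uniform sampling and infers the sampling
rate from the timestamps; writing uses 12 significant digits so a
write→read round trip is an identity at that precision.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .model import NonUniformSamplingError, Waveform
from .synthetic import LabeledDataset

__all__ = ["WAVEFORM_HEADER", "read_waveform_csv", "write_waveform_csv", "write_corpus"]

WAVEFORM_HEADER = ("time_s", "flow_ml_s", "paw_cmh2o")


def read_waveform_csv(path) -> Waveform:
    """Read a waveform CSV, validating the header, numeric cells and uniform sampling."""
    df = pd.read_csv(path)
    if tuple(df.columns) != WAVEFORM_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(WAVEFORM_HEADER)}, got {','.join(df.columns)}"
        )
    for col in WAVEFORM_HEADER:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value in column {col} at data row {row}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value in column {col} at data row {row}")
        df[col] = numeric
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = (t.size - 1) / (t[-1] - t[0]) if t[-1] != t[0] else float("nan")
    if not np.isfinite(fs) or fs <= 0:
        raise NonUniformSamplingError(f"{path}: timestamps do not advance")
    try:
        return Waveform(t, df["flow_ml_s"].to_numpy(), df["paw_cmh2o"].to_numpy(), fs)
    except NonUniformSamplingError as exc:
        raise NonUniformSamplingError(f"{path}: {exc}") from exc


def write_waveform_csv(wave: Waveform, path) -> None:
    """Write a waveform as CSV with 12 significant digits."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(WAVEFORM_HEADER) + "\n")
        for ti, fi, pi in zip(wave.t, wave.flow, wave.paw):
            fh.write(f"{ti:.12g},{fi:.12g},{pi:.12g}\n")


def write_corpus(datasets: list[LabeledDataset], out_dir, seed: int | None = None) -> str:
    """Write one waveform CSV per dataset plus a manifest CSV; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for ds in datasets:
        name = f"set{ds.param_set_id:04d}_noise{ds.noise_set_id:02d}.csv"
        write_waveform_csv(ds.waveform, os.path.join(out_dir, name))
        p = ds.true_params
        rows.append(
            {
                "param_set_id": ds.param_set_id,
                "noise_set_id": ds.noise_set_id,
                "R1": p.R1,
                "C1": p.C1,
                "R2": p.R2,
                "C2": p.C2,
                "seed": seed if seed is not None else "",
                "file": name,
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
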