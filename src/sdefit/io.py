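"""File I/O: time series (CSV / HDF5), model JSON, config files."""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .models import LangevinModel
from .moments import BinnedMoments, EmpiricalPDF, TimeSeries

__all__ = [
    "ParseError",
    "load_timeseries",
    "save_timeseries",
    "save_model",
    "load_model",
    "load_config_file",
    "save_moments_table",
    "save_pdf_table",
]


class ParseError(ValueError):
    pass


_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def _from_frame(df: pd.DataFrame, path, dt, column):
    if column is not None:
        if column not in df.columns:
            raise ParseError(f"{path}: no column named {column!r}")
        col = column
    elif "x" in df.columns:
        col = "x"
    elif len(df.columns) == 1:
        col = df.columns[0]
    else:
        col = df.columns[-1]
    raw = df[col]
    try:
        values = raw.astype(float).to_numpy()
    except (ValueError, TypeError):
        for i, v in enumerate(raw):
            try:
                float(v)
            except (ValueError, TypeError):
                # +2: header line plus 1-based numbering
                raise ParseError(
                    f"{path}: non-numeric entry {v!r} in column {col!r} "
                    f"at line {i + 2}"
                ) from None
        raise
    if dt is None:
        for tname in ("time", "t"):
            if tname in df.columns:
                tvals = df[tname].astype(float).to_numpy()
                steps = np.diff(tvals)
                if steps.size and np.allclose(steps, steps[0], rtol=1e-6):
                    dt = float(steps[0])
                break
    if dt is None:
        raise ParseError(
            f"{path}: sampling interval dt not given and not inferable"
        )
    return TimeSeries(values=values, dt=dt, label=str(path))


def load_timeseries(
    path, dt: float | None = None, column: str | None = None
) -> TimeSeries:
    """Read a trajectory from delimited text (header row) or HDF5.

    For text input, the state column is ``column`` if given, else ``x``,
    else the single/last column; dt is taken from the argument or inferred
    from a uniform ``time``/``t`` column.  For HDF5, the first 1D float
    dataset is used and dt comes from its (or the file's) ``dt`` attribute
    unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as fh:
            name = column
            if name is None:
                for key, node in fh.items():
                    if isinstance(node, h5py.Dataset) and node.ndim == 1:
                        name = key
                        break
            if name is None or name not in fh:
                raise ParseError(f"{path}: no 1D dataset found")
            dset = fh[name]
            values = np.asarray(dset[...], dtype=float)
            file_dt = dset.attrs.get("dt", fh.attrs.get("dt", None))
            if dt is None:
                if file_dt is None:
                    raise ParseError(f"{path}: no dt attribute and none given")
                dt = float(file_dt)
        return TimeSeries(values=values, dt=dt, label=str(path))
    import csv

    try:
        sample = path.read_text()[:4096]
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
        except csv.Error:
            sep = r"\s+" if " " in sample.splitlines()[0] else ","
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: could not parse delimited text: {exc}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return _from_frame(df, path, dt, column)


def save_timeseries(ts: TimeSeries, path) -> None:
    """Write as two-column CSV (time, x) or as an HDF5 dataset with dt attr."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("x", data=ts.values)
            dset.attrs["dt"] = ts.dt
    else:
        pd.DataFrame({"time": ts.times, "x": ts.values}).to_csv(
            path, index=False
        )


def save_model(model: LangevinModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")


def load_model(path) -> LangevinModel:
    with open(path) as fh:
        return LangevinModel.from_dict(json.load(fh))


def load_config_file(path) -> dict:
    """YAML or JSON config, auto-detected by suffix then content."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def save_moments_table(binned: BinnedMoments, path) -> None:
    pd.DataFrame(
        {
            "bin_center": binned.grid.centers,
            "count": binned.counts,
            "m1": binned.m1,
            "m2": binned.m2,
            "w1": binned.weights1,
            "w2": binned.weights2,
            "valid": binned.valid.astype(int),
        }
    ).to_csv(path, index=False)


def save_pdf_table(path, grid_centers, columns: dict) -> None:
    pd.DataFrame({"x": grid_centers, **columns}).to_csv(path, index=False)
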