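"""Delimited-text I/O for spectra, SCRS, manifests and symptom tables.

Two interchange layouts are supported for raw spectra:

* ``wide`` -- first column ``wavenumber``; every other column is one
  acquisition, headed ``subject:cell:acquisition``.
* ``long`` -- tidy columns ``subject_id, cell_id, acquisition_id,
  wavenumber, intensity``.

CSV vs TSV is auto-detected from the file extension.  Values round-trip
losslessly (17-significant-digit doubles, round-trip parsing).  Vendor binary formats
(SPC, WDF) are deliberately not parsed; export to text first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CellSpectrum, RawSpectrum, SpectralAxis

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_cell_spectra",
    "write_cell_spectra",
    "read_manifest",
    "write_manifest",
]

_SEP = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _sep_for(path) -> str:
    return _SEP.get(Path(path).suffix.lower(), ",")


def _axis_from_column(values: np.ndarray) -> SpectralAxis:
    if not np.all(np.diff(values) > 0):
        raise ValueError("wavenumber column must be strictly increasing")
    return SpectralAxis(np.asarray(values, dtype=float))


def write_spectra(path, axis: SpectralAxis, spectra: list[RawSpectrum], format: str = "wide") -> None:
    sep = _sep_for(path)
    for s in spectra:
        if s.axis != axis:
            raise ValueError(f"spectrum {s.key} not on the shared axis")
    if format == "wide":
        data = {"wavenumber": axis.wavenumbers}
        for s in spectra:
            col = f"{s.subject_id}:{s.cell_id}:{s.acquisition_id}"
            if col in data:
                raise ValueError(f"duplicate acquisition key {col}")
            data[col] = s.intensities
        pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
    elif format == "long":
        frames = [
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "cell_id": s.cell_id,
                    "acquisition_id": s.acquisition_id,
                    "wavenumber": axis.wavenumbers,
                    "intensity": s.intensities,
                }
            )
            for s in spectra
        ]
        cols = ["subject_id", "cell_id", "acquisition_id", "wavenumber", "intensity"]
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
        out.to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_spectra(path, format: str = "wide") -> tuple[SpectralAxis, list[RawSpectrum]]:
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if format == "wide":
        if df.shape[1] < 2:
            raise ValueError("wide file needs a wavenumber column plus >= 1 spectrum")
        axis = _axis_from_column(df.iloc[:, 0].to_numpy(dtype=float))
        spectra: list[RawSpectrum] = []
        seen: set[str] = set()
        for col in df.columns[1:]:
            if col in seen:
                raise ValueError(f"duplicate acquisition key {col}")
            seen.add(col)
            parts = col.split(":")
            if len(parts) != 3:
                raise ValueError(f"column header {col!r} is not subject:cell:acquisition")
            y = df[col].to_numpy(dtype=float)
            if np.isnan(y).any():
                raise ValueError(f"ragged/missing values in column {col!r}")
            spectra.append(RawSpectrum(axis, y, *parts))
        return axis, spectra
    if format == "long":
        need = {"subject_id", "cell_id", "acquisition_id", "wavenumber", "intensity"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"long file missing columns {sorted(missing)}")
        spectra = []
        axis = None
        for key, grp in df.groupby(["subject_id", "cell_id", "acquisition_id"], sort=False):
            grp = grp.sort_values("wavenumber")
            ax = _axis_from_column(grp["wavenumber"].to_numpy(dtype=float))
            if axis is None:
                axis = ax
            elif ax != axis:
                raise ValueError(f"acquisition {key} is on a different axis")
            spectra.append(
                RawSpectrum(axis, grp["intensity"].to_numpy(dtype=float), *(str(k) for k in key))
            )
        if axis is None:
            raise ValueError("long file contains no spectra")
        keys = [s.key for s in spectra]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate acquisition keys in long file")
        return axis, spectra
    raise ValueError(f"unknown format {format!r}")


def write_cell_spectra(path, cells: list[CellSpectrum]) -> None:
    """Wide CSV of SCRS; header ``subject:cell:n_acquisitions``."""
    if not cells:
        pd.DataFrame({"wavenumber": []}).to_csv(path, sep=_sep_for(path), index=False)
        return
    axis = cells[0].axis
    data = {"wavenumber": axis.wavenumbers}
    for c in cells:
        if c.axis != axis:
            raise ValueError("mixed axes in SCRS set")
        data[f"{c.subject_id}:{c.cell_id}:{c.n_acquisitions}"] = c.intensities
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_cell_spectra(path, normalized: bool = True) -> tuple[SpectralAxis, list[CellSpectrum]]:
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    axis = _axis_from_column(df.iloc[:, 0].to_numpy(dtype=float))
    cells = []
    for col in df.columns[1:]:
        subject, cell, n_acq = col.split(":")
        cells.append(
            CellSpectrum(
                axis,
                df[col].to_numpy(dtype=float),
                cell_id=cell,
                subject_id=subject,
                n_acquisitions=int(n_acq),
                normalized=normalized,
            )
        )
    return axis, cells


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep=_sep_for(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("manifest needs subject_id and group columns")
    return df
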