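"""Core spectral containers.

A :class:`SpectralAxis` is the shared wavenumber grid (Raman shift, cm^-1)
on which every spectrum in a cohort lives.  The canonical grid used
throughout the package spans 319-3401 cm^-1 in 1019 uniform channels
(step ~3.027 cm^-1), the working range of a dispersive confocal Raman
microscope with a 532 nm excitation line.

Two spectrum types are distinguished:

* :class:`RawSpectrum` -- one acquisition (a few seconds of CCD exposure at
  one spot inside a cell), identified by subject/cell/acquisition ids.
* :class:`CellSpectrum` -- the single-cell Raman spectrum (SCRS): the
  channel-wise average of all acquisitions within one cell, optionally
  L2-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpectralAxis",
    "RawSpectrum",
    "CellSpectrum",
    "make_canonical_axis",
    "canonical_axis",
    "resample_to_axis",
]


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("axis needs at least 2 channels")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)

    @property
    def n_channels(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def step(self) -> float:
        """Mean channel spacing in cm^-1."""
        return float((self.wavenumbers[-1] - self.wavenumbers[0]) / (self.n_channels - 1))

    def window(self, start: float, end: float) -> np.ndarray:
        """Indices of channels with start <= wavenumber <= end."""
        if end < start:
            raise ValueError(f"empty window ({start}, {end})")
        return np.flatnonzero((self.wavenumbers >= start) & (self.wavenumbers <= end))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.array_equal(self.wavenumbers, other.wavenumbers)
        )

    def __len__(self) -> int:
        return self.n_channels


def make_canonical_axis(start: float, end: float, n_channels: int) -> SpectralAxis:
    """Uniform axis from ``start`` to ``end`` cm^-1 inclusive.

    (319, 3401, 1019) reproduces the canonical PBMC acquisition grid with a
    step of (3401-319)/1018 ~ 3.027 cm^-1.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if end <= start:
        raise ValueError("end must exceed start")
    return SpectralAxis(np.linspace(float(start), float(end), int(n_channels)))


def canonical_axis() -> SpectralAxis:
    """The default 319-3401 cm^-1, 1019-channel grid."""
    return make_canonical_axis(319.0, 3401.0, 1019)


def _check_intensities(axis: SpectralAxis, intensities: np.ndarray) -> np.ndarray:
    y = np.asarray(intensities, dtype=float)
    if y.shape != (axis.n_channels,):
        raise ValueError(
            f"intensities length {y.shape} does not match axis ({axis.n_channels},)"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    return y


@dataclass
class RawSpectrum:
    """One acquisition: intensities (a.u.) on a shared axis plus identity."""

    axis: SpectralAxis
    intensities: np.ndarray
    subject_id: str
    cell_id: str
    acquisition_id: str
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.intensities = _check_intensities(self.axis, self.intensities)

    def with_intensities(self, y: np.ndarray, flag: str | None = None) -> "RawSpectrum":
        flags = set(self.qc_flags) | ({flag} if flag else set())
        return replace(self, intensities=np.asarray(y, dtype=float), qc_flags=flags)

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.cell_id, self.acquisition_id)


@dataclass
class CellSpectrum:
    """Single-cell Raman spectrum: mean of a cell's acquisitions."""

    axis: SpectralAxis
    intensities: np.ndarray
    cell_id: str
    subject_id: str
    n_acquisitions: int = 1
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = _check_intensities(self.axis, self.intensities)
        if self.n_acquisitions < 1:
            raise ValueError("n_acquisitions must be >= 1")
        if self.normalized:
            norm = float(np.linalg.norm(self.intensities))
            if abs(norm - 1.0) > 1e-9:
                raise ValueError(f"normalized spectrum has L2 norm {norm}")


def resample_to_axis(spectrum: RawSpectrum, target: SpectralAxis) -> RawSpectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Target channels outside the source range are filled with the edge value
    and the spectrum is flagged ``resampled_edge``.  At least two target
    channels must fall inside the source range.
    """
    src = spectrum.axis.wavenumbers
    if target == spectrum.axis:
        return spectrum
    inside = (target.wavenumbers >= src[0]) & (target.wavenumbers <= src[-1])
    if int(inside.sum()) < 2:
        raise ValueError("source and target axes overlap in fewer than 2 channels")
    y = np.interp(target.wavenumbers, src, spectrum.intensities)
    out = RawSpectrum(
        axis=target,
        intensities=y,
        subject_id=spectrum.subject_id,
        cell_id=spectrum.cell_id,
        acquisition_id=spectrum.acquisition_id,
        qc_flags=set(spectrum.qc_flags),
    )
    if not bool(inside.all()):
        out.qc_flags.add("resampled_edge")
    return out
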