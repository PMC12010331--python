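"""Domain containers and file I/O for spectro-temporal data.

The central object is :class:`SpectralTimeMatrix`: differential absorbance
ΔA(λ, t) in mOD on a strictly increasing wavelength axis (nm) and delay axis
(ps), indexed ``values[delay, wavelength]``.  Time is picoseconds everywhere
inside the package; readers convert from seconds when the file declares them
(CSV header cell ``delay_s``, HDF5 attribute ``time_unit = "s"``).  Delay
t = 0 is the instrument-response center, so negative delays (pre-excitation
baseline) are legal and expected.

Two on-disk layouts are supported:

* CSV — first cell the literal ``delay_ps`` (or ``delay_s``), remainder of
  row 1 the wavelengths in nm; every following row a delay then the ΔA values
  in mOD.  UTF-8, ``.`` decimal, comma separator.
* HDF5 — datasets ``/wavelengths_nm``, ``/delays_ps``, ``/delta_A_mOD``
  with optional root attributes ``pump_nm`` and ``label``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .exceptions import (
    AxisMismatchError,
    DuplicateAxisError,
    EmptySliceError,
    EmptyWindowError,
    FormatError,
    ParameterError,
)

__all__ = [
    "SpectralTimeMatrix",
    "Spectrum",
    "AnalysisConfig",
    "read_matrix",
    "write_matrix",
    "slice_spectral",
    "difference_spectrum",
    "time_average_window",
]


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1:
        raise ParameterError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(axis)):
        raise ParameterError(f"{name} contains non-finite values")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ParameterError(f"{name} must be strictly increasing")
    return axis


@dataclass
class SpectralTimeMatrix:
    """ΔA(λ, t) on a wavelength × delay grid.

    Attributes
    ----------
    wavelengths : array, nm, strictly increasing
    delays : array, ps, strictly increasing (t = 0 at the IRF center)
    values : 2-D array, mOD, shape (len(delays), len(wavelengths))
    pump_nm : optional excitation wavelength, nm
    label : free-text tag
    """

    wavelengths: np.ndarray
    delays: np.ndarray
    values: np.ndarray
    pump_nm: float | None = None
    label: str = ""

    def __post_init__(self):
        self.wavelengths = _check_axis("wavelengths", self.wavelengths)
        self.delays = _check_axis("delays", self.delays)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.delays.size, self.wavelengths.size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"(n_delays, n_wavelengths) = "
                f"({self.delays.size}, {self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values contain non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "SpectralTimeMatrix":
        return SpectralTimeMatrix(
            self.wavelengths.copy(),
            self.delays.copy(),
            self.values.copy(),
            self.pump_nm,
            self.label,
        )


@dataclass
class Spectrum:
    """A single spectrum: values (ΔA or A) on a wavelength axis."""

    wavelengths: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ParameterError("wavelengths and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("spectrum values contain non-finite entries")


@dataclass
class AnalysisConfig:
    """Knobs shared by the analysis pipelines.

    Lifetime grid: log-spaced from ``tau_min_ps`` to ``tau_max_ps`` with
    ``points_per_decade`` points per decade (default 0.02–1000 ps, 20/decade).
    ``entropy_prior_frac`` sets the maximum-entropy zero scale m as a fraction
    of each wavelength's peak |ΔA|.  The regularization scan covers
    ``alpha_decades`` decades with ``n_alphas`` points.  ``floor_ps`` is the
    shortest lifetime treated as dynamical rather than instrumental.
    """

    tau_min_ps: float = 0.02
    tau_max_ps: float = 1000.0
    points_per_decade: int = 20
    entropy_prior_frac: float = 0.01
    n_alphas: int = 25
    alpha_decades: float = 6.0
    irf_t0_ps: float = 0.0
    irf_fwhm_ps: float = 0.10
    floor_ps: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.tau_min_ps < self.tau_max_ps):
            raise ParameterError("lifetime grid bounds must satisfy 0 < min < max")
        if self.points_per_decade < 1:
            raise ParameterError("points_per_decade must be >= 1")
        if self.floor_ps < 0:
            raise ParameterError("floor_ps must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a plain ``key: value`` text file (a YAML mapping subset)."""
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# readers / writers


def _sort_axes(
    wavelengths: np.ndarray, delays: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iw = np.argsort(wavelengths)
    it = np.argsort(delays)
    wavelengths, delays = wavelengths[iw], delays[it]
    values = values[np.ix_(it, iw)]
    for name, axis in (("wavelength", wavelengths), ("delay", delays)):
        if axis.size > 1 and np.any(np.diff(axis) <= 0):
            dup = axis[np.where(np.diff(axis) <= 0)[0][0]]
            raise DuplicateAxisError(f"duplicate {name} value {dup!r} in axis")
    return wavelengths, delays, values


def _read_csv(path: Path) -> SpectralTimeMatrix:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] not in ("delay_ps", "delay_s"):
        raise FormatError(
            f"{path}: line 1 must start with 'delay_ps' (or 'delay_s'), "
            f"got {header[0]!r}" if header else f"{path}: empty header row"
        )
    time_scale = 1.0 if header[0] == "delay_ps" else 1e12
    try:
        wavelengths = np.array([float(x) for x in header[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength in header: {exc}") from exc
    ncol = wavelengths.size
    delays, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != ncol + 1:
            raise FormatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {ncol + 1}"
            )
        try:
            delays.append(float(row[0]) * time_scale)
            data.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric value: {exc}") from exc
    if not data:
        raise FormatError(f"{path}: no data rows")
    w, t, v = _sort_axes(wavelengths, np.array(delays), np.array(data))
    return SpectralTimeMatrix(w, t, v)


def _read_hdf5(path: Path) -> SpectralTimeMatrix:
    with h5py.File(path, "r") as fh:
        for name in ("wavelengths_nm", "delays_ps", "delta_A_mOD"):
            if name not in fh:
                raise FormatError(f"{path}: missing dataset /{name}")
        wavelengths = fh["wavelengths_nm"][()].astype(float)
        delays = fh["delays_ps"][()].astype(float)
        values = fh["delta_A_mOD"][()].astype(float)
        if str(fh.attrs.get("time_unit", "ps")) == "s":
            delays = delays * 1e12
        pump = fh.attrs.get("pump_nm", None)
        pump_nm = float(pump) if pump is not None else None
        label = str(fh.attrs.get("label", ""))
    if values.shape != (delays.size, wavelengths.size):
        raise FormatError(
            f"{path}: /delta_A_mOD shape {values.shape} does not match axes"
        )
    w, t, v = _sort_axes(wavelengths, delays, values)
    return SpectralTimeMatrix(w, t, v, pump_nm=pump_nm, label=label)


def read_matrix(path: str | Path, format: str | None = None) -> SpectralTimeMatrix:
    """Read a ΔA matrix from CSV or HDF5.

    ``format`` is ``"csv"`` or ``"hdf5"``; when None it is inferred from the
    file suffix.  Axes are sorted ascending; duplicated axis values raise
    :class:`DuplicateAxisError`, layout violations raise :class:`FormatError`
    naming the offending line or dataset.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = format or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ParameterError(f"unknown format {fmt!r}")


def write_matrix(
    matrix: SpectralTimeMatrix, path: str | Path, format: str | None = None
) -> Path:
    """Write a matrix; re-readable by :func:`read_matrix` with axes exact
    and values reproduced to better than 1e-9 mOD."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["delay_ps"] + [repr(float(w)) for w in matrix.wavelengths]
            )
            for t, row in zip(matrix.delays, matrix.values):
                writer.writerow([repr(float(t))] + [repr(float(v)) for v in row])
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("wavelengths_nm", data=matrix.wavelengths)
            fh.create_dataset("delays_ps", data=matrix.delays)
            fh.create_dataset("delta_A_mOD", data=matrix.values)
            if matrix.pump_nm is not None:
                fh.attrs["pump_nm"] = float(matrix.pump_nm)
            if matrix.label:
                fh.attrs["label"] = matrix.label
    else:
        raise ParameterError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# spectral arithmetic


def slice_spectral(
    matrix: SpectralTimeMatrix, lo_nm: float, hi_nm: float
) -> SpectralTimeMatrix:
    """Restrict the wavelength axis to [lo_nm, hi_nm], bounds inclusive."""
    if not lo_nm < hi_nm:
        raise ParameterError("require lo_nm < hi_nm")
    mask = (matrix.wavelengths >= lo_nm) & (matrix.wavelengths <= hi_nm)
    if not mask.any():
        raise EmptySliceError(f"no wavelengths in [{lo_nm}, {hi_nm}] nm")
    return SpectralTimeMatrix(
        matrix.wavelengths[mask],
        matrix.delays.copy(),
        matrix.values[:, mask],
        matrix.pump_nm,
        matrix.label,
    )


def difference_spectrum(a: Spectrum, ref: Spectrum) -> Spectrum:
    """a − ref, elementwise; the axes must agree to 1e-6 nm (no interpolation)."""
    if a.wavelengths.size != ref.wavelengths.size or not np.allclose(
        a.wavelengths, ref.wavelengths, atol=1e-6, rtol=0
    ):
        raise AxisMismatchError("wavelength axes differ; interpolate explicitly first")
    return Spectrum(a.wavelengths.copy(), a.values - ref.values,
                    label=f"{a.label} - {ref.label}".strip(" -"))


def time_average_window(
    matrix: SpectralTimeMatrix, t_lo: float, t_hi: float
) -> Spectrum:
    """Mean transient spectrum over delays t_lo ≤ t ≤ t_hi (inclusive)."""
    mask = (matrix.delays >= t_lo) & (matrix.delays <= t_hi)
    if not mask.any():
        raise EmptyWindowError(f"no delays in [{t_lo}, {t_hi}] ps")
    return Spectrum(
        matrix.wavelengths.copy(),
        matrix.values[mask].mean(axis=0),
        label=f"mean {t_lo}-{t_hi} ps",
    )
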