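"""Corrections applied to ΔA matrices before kinetic analysis.

Order of a typical pipeline: solvent/background subtraction, chirp
estimation and correction, optional logarithmic time averaging, and
baseline noise estimation from the pre-excitation rows.

The supercontinuum probe is chirped: its arrival time t0 depends on
wavelength.  We locate time zero per wavelength as the delay of the
steepest signal change inside the IRF window (this works whether or not a
coherent artifact is present), fit a cubic polynomial t0(λ), and
re-interpolate every wavelength column onto the common delay axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SpectralTimeMatrix
from .exceptions import (
    AxisMismatchError,
    InsufficientBaselineError,
    ParameterError,
)

__all__ = [
    "ChirpCurve",
    "estimate_chirp",
    "apply_chirp",
    "subtract_reference",
    "log_average",
    "estimate_noise",
]


@dataclass
class ChirpCurve:
    """Cubic t0(λ) in ps versus normalized wavelength u = (λ − λ_min)/span."""

    coefficients: np.ndarray  # ascending powers of u
    lambda_min: float
    lambda_span: float
    rms_residual_ps: float = 0.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ParameterError("chirp coefficients must be finite")

    def t0(self, wavelengths) -> np.ndarray:
        u = (np.asarray(wavelengths, float) - self.lambda_min) / self.lambda_span
        return np.polyval(self.coefficients[::-1], u)


def estimate_chirp(
    matrix: SpectralTimeMatrix, window_ps: float = 0.6, degree: int = 3
) -> ChirpCurve:
    """Estimate the probe chirp t0(λ).

    Per wavelength the time-zero marker is the delay of maximum |d(ΔA)/dt|
    within ±``window_ps`` of zero (the signal rise and the coherent artifact
    are both steepest there); a least-squares polynomial in normalized
    wavelength smooths the markers across the spectrum.  Columns are
    weighted by their slope amplitude, so signal-free wavelengths (whose
    markers are noise) barely influence the curve.
    """
    t = matrix.delays
    if t.min() >= 0:
        raise InsufficientBaselineError(
            "chirp estimation needs delays bracketing time zero"
        )
    sel = (t >= -window_ps) & (t <= window_ps)
    if sel.sum() < 4:
        raise InsufficientBaselineError("too few delays inside the IRF window")
    tw = t[sel]
    tmid = 0.5 * (tw[1:] + tw[:-1])
    slopes = np.abs(np.diff(matrix.values[sel], axis=0) / np.diff(tw)[:, None])
    idx = np.argmax(slopes, axis=0)
    markers = tmid[idx]
    # sub-step refinement: parabola through the slope maximum and neighbors
    for k in range(markers.size):
        i = idx[k]
        if 0 < i < slopes.shape[0] - 1:
            y0, y1, y2 = slopes[i - 1, k], slopes[i, k], slopes[i + 1, k]
            den = y0 - 2 * y1 + y2
            if den < 0:
                shift = 0.5 * (y0 - y2) / den
                markers[k] = tmid[i] + np.clip(shift, -1, 1) * (
                    tmid[min(i + 1, len(tmid) - 1)] - tmid[i]
                )
    span = matrix.wavelengths[-1] - matrix.wavelengths[0]
    span = span if span > 0 else 1.0
    u = (matrix.wavelengths - matrix.wavelengths[0]) / span
    deg = min(degree, max(u.size - 1, 0))
    strength = slopes.max(axis=0)
    weights = strength / max(strength.max(), 1e-300)
    coeffs = np.polyfit(u, markers, deg, w=weights)[::-1]
    fit = np.polyval(coeffs[::-1], u)
    wsum = weights.sum()
    rms = float(np.sqrt(np.sum(weights * (markers - fit) ** 2) / wsum))
    return ChirpCurve(
        coefficients=coeffs,
        lambda_min=matrix.wavelengths[0],
        lambda_span=span,
        rms_residual_ps=rms,
    )


def apply_chirp(matrix: SpectralTimeMatrix, curve: ChirpCurve) -> SpectralTimeMatrix:
    """Shift every wavelength column by −t0(λ) onto the common delay axis.

    Linear interpolation; cells shifted out of the recorded range are filled
    with that column's pre-zero baseline mean.
    """
    t0 = curve.t0(matrix.wavelengths)
    t = matrix.delays
    out = np.empty_like(matrix.values)
    pre = t < 0
    for i in range(matrix.wavelengths.size):
        col = matrix.values[:, i]
        baseline = float(col[pre].mean()) if pre.any() else float(col[0])
        out[:, i] = np.interp(t + t0[i], t, col, left=baseline, right=baseline)
    return SpectralTimeMatrix(
        matrix.wavelengths.copy(), t.copy(), out, matrix.pump_nm, matrix.label
    )


def subtract_reference(
    matrix: SpectralTimeMatrix, reference: SpectralTimeMatrix
) -> SpectralTimeMatrix:
    """Elementwise subtraction of a solvent/buffer measurement on identical axes."""
    if (
        matrix.wavelengths.size != reference.wavelengths.size
        or matrix.delays.size != reference.delays.size
        or not np.allclose(matrix.wavelengths, reference.wavelengths, atol=1e-6)
        or not np.allclose(matrix.delays, reference.delays, atol=1e-9)
    ):
        raise AxisMismatchError("sample and reference matrices must share axes")
    return SpectralTimeMatrix(
        matrix.wavelengths.copy(),
        matrix.delays.copy(),
        matrix.values - reference.values,
        matrix.pump_nm,
        matrix.label,
    )


def log_average(
    matrix: SpectralTimeMatrix, points_per_decade: int, t_linear: float
) -> SpectralTimeMatrix:
    """Logarithmically average the delay axis beyond ``t_linear``.

    Delays ≤ t_linear are kept untouched; later delays fall into log-uniform
    bins (``points_per_decade`` per decade); each output row is the
    arithmetic mean of its member rows and is placed at the geometric mean
    of the member delays.  Empty bins are dropped.
    """
    if points_per_decade < 1:
        raise ParameterError("points_per_decade must be >= 1")
    t = matrix.delays
    # non-positive delays are always kept as-is (log binning needs t > 0)
    keep = (t <= t_linear) | (t <= 0)
    rows = [matrix.values[keep]]
    times = [t[keep]]
    late = t[~keep]
    late_vals = matrix.values[~keep]
    if late.size:
        start = max(t_linear, np.nextafter(0, 1))
        decades = np.log10(late / start)
        idx = np.floor(decades * points_per_decade).astype(int)
        for b in np.unique(idx):
            sel = idx == b
            times.append([np.exp(np.mean(np.log(late[sel])))])
            rows.append(late_vals[sel].mean(axis=0, keepdims=True))
    delays = np.concatenate(times)
    values = np.vstack(rows)
    order = np.argsort(delays)
    return SpectralTimeMatrix(
        matrix.wavelengths.copy(),
        delays[order],
        values[order],
        matrix.pump_nm,
        matrix.label,
    )


def estimate_noise(
    matrix: SpectralTimeMatrix,
    irf_fwhm_ps: float = 0.10,
    floor_mOD: float = 1e-6,
    min_rows: int = 5,
) -> np.ndarray:
    """Per-wavelength noise SD from the pre-excitation baseline.

    Uses all rows earlier than −2 × IRF width; the result is floored at
    ``floor_mOD`` so downstream χ² weights stay finite on noiseless data.
    """
    pre = matrix.delays < -2.0 * irf_fwhm_ps
    if pre.sum() < min_rows:
        raise InsufficientBaselineError(
            f"need at least {min_rows} delays earlier than "
            f"{-2 * irf_fwhm_ps:.3g} ps, found {int(pre.sum())}"
        )
    sd = matrix.values[pre].std(axis=0, ddof=1)
    return np.maximum(sd, floor_mOD)
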