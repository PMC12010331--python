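"""Global kinetic analysis of transient-absorption matrices.

The forward model is a sum of exponential decays convolved with a Gaussian
instrument response function (IRF).  The convolution has the closed form

    c(t) = 1/2 · exp(σ²/(2τ²) − Δ/τ) · [1 + erf((Δ − σ²/τ)/(σ√2))],

with Δ = t − t0 and σ the Gaussian standard deviation; it is evaluated here
through scipy's scaled complementary error function (erfcx) so that it stays
finite for τ ≪ σ and far pre-zero delays.

Fitting uses variable projection: for a trial set of lifetimes and IRF
parameters the decay-associated difference spectra (DADS) are the exact
weighted linear-least-squares solution per wavelength, and only the handful
of nonlinear parameters (log-lifetimes, t0, IRF width) are iterated.  The
number of components is chosen by singular value decomposition of the
noise-whitened matrix.  A sequential irreversible scheme 1 → 2 → … → n
converts DADS into evolution-associated difference spectra (EADS) and
species concentration profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, erfcx

import lmfit

from .core_io import SpectralTimeMatrix, Spectrum
from .exceptions import (
    ConvergenceError,
    DegenerateRatesError,
    DegeneracyWarning,
    ParameterError,
)

__all__ = [
    "IRFModel",
    "ComponentSpectra",
    "ConcentrationProfiles",
    "KineticFitResult",
    "irf_convolved_exponential",
    "svd_rank",
    "global_fit",
    "sequential_concentrations",
    "species_fractions",
    "dads_to_eads",
]

_SQRT2 = np.sqrt(2.0)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: center ``t0`` and ``fwhm``, both ps."""

    t0: float = 0.0
    fwhm: float = 0.10

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ParameterError("IRF fwhm must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm * _FWHM_TO_SIGMA

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Unit-area Gaussian evaluated at t (ps)."""
        s = self.sigma
        return np.exp(-0.5 * ((np.asarray(t) - self.t0) / s) ** 2) / (
            s * np.sqrt(2 * np.pi)
        )


@dataclass
class ComponentSpectra:
    """Per-component spectra, either DADS (parallel decomposition) or EADS
    (sequential scheme), each tagged with its lifetime in ps."""

    kind: str  # "DADS" or "EADS"
    lifetimes: np.ndarray
    spectra: list[Spectrum]

    def __post_init__(self):
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        if self.kind not in ("DADS", "EADS"):
            raise ParameterError("kind must be 'DADS' or 'EADS'")
        if self.lifetimes.size != len(self.spectra):
            raise ParameterError("one lifetime per spectrum required")
        if len(self.spectra) > 1:
            ax = self.spectra[0].wavelengths
            for s in self.spectra[1:]:
                if s.wavelengths.shape != ax.shape or not np.allclose(
                    s.wavelengths, ax
                ):
                    raise ParameterError("component spectra must share one axis")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def as_array(self) -> np.ndarray:
        """Stack to shape (n_components, n_wavelengths)."""
        return np.vstack([s.values for s in self.spectra])


@dataclass
class ConcentrationProfiles:
    """Dimensionless species populations c[delay, component]."""

    delays: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape[0] != self.delays.size:
            raise ParameterError("profile rows must match delay axis")
        if not np.all(np.isfinite(self.c)):
            raise ParameterError("concentration profiles contain non-finite values")


@dataclass
class KineticFitResult:
    lifetimes: np.ndarray
    irf: IRFModel
    dads: ComponentSpectra
    chi2_reduced: float
    residuals: np.ndarray  # (n_delays, n_wavelengths), noise-whitened
    covariance: np.ndarray | None = None
    artifact_amplitudes: np.ndarray | None = None  # (n_art, n_wavelengths)


def irf_convolved_exponential(
    t: np.ndarray | float, tau: float, irf: IRFModel
) -> np.ndarray | float:
    """Exponential decay exp(−Δ/τ)·H(Δ) convolved with a Gaussian IRF.

    Values lie in [0, 1]; the function rises smoothly through t0 over the
    IRF width and matches the plain exponential once Δ ≫ σ.
    """
    if tau <= 0:
        raise ParameterError("tau must be positive")
    t = np.asarray(t, dtype=float)
    sigma = irf.sigma
    delta = t - irf.t0
    z = (sigma / tau - delta / sigma) / _SQRT2
    # z >= 0 (pre-zero or tau << sigma): erfcx form avoids exp overflow of
    # the naive expression; z < 0 (well past zero): the naive exponent is
    # negative, so the direct erfc form is safe and erfcx would overflow.
    zz = np.atleast_1d(z)
    dd = np.atleast_1d(delta)
    pos = zz >= 0
    out = np.empty_like(zz)
    out[pos] = 0.5 * erfcx(zz[pos]) * np.exp(-0.5 * (dd[pos] / sigma) ** 2)
    neg = ~pos
    expo = sigma**2 / (2 * tau**2) - dd[neg] / tau
    out[neg] = 0.5 * np.exp(expo) * erfc(zz[neg])
    out = np.clip(out, 0.0, 1.0)
    return out if np.asarray(t).ndim else float(out[0])


def artifact_columns(delays, irf: IRFModel, order: int = 1) -> np.ndarray:
    """Coherent-artifact basis: a unit-peak Gaussian at the IRF center and
    its first ``order`` time derivatives (each scaled to unit peak).

    Cross-phase modulation and the coherent artifact are localized within
    the IRF window; explicit columns keep their amplitude from leaking into
    the kinetic components.
    """
    delays = np.asarray(delays, dtype=float)
    s = irf.sigma
    x = (delays - irf.t0) / s
    g = np.exp(-0.5 * x**2)
    cols = [g]
    if order >= 1:
        cols.append(-x * g * np.exp(0.5))
    if order >= 2:
        cols.append((x**2 - 1.0) * g)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# rank selection


def _mp_median(beta: float) -> float:
    """Median of the Marchenko–Pastur eigenvalue law (unit variance),
    aspect ratio beta = n/m in (0, 1]."""
    from scipy.integrate import quad
    from scipy.optimize import brentq

    lo = (1 - np.sqrt(beta)) ** 2
    hi = (1 + np.sqrt(beta)) ** 2

    def dens(x):
        return np.sqrt(np.maximum((hi - x) * (x - lo), 0.0)) / (2 * np.pi * beta * x)

    def cdf_minus_half(x):
        val, _ = quad(dens, lo, x, limit=200)
        return val - 0.5

    return brentq(cdf_minus_half, lo + 1e-12, hi - 1e-12)


def svd_rank(
    matrix: SpectralTimeMatrix, noise: np.ndarray
) -> tuple[int, np.ndarray]:
    """Number of resolvable kinetic components by SVD of the whitened matrix.

    Each wavelength column is divided by its noise SD; singular values of the
    whitened matrix are compared with the Marchenko–Pastur bulk edge
    σ̂·(√m + √n) plus a Tracy–Widom finite-size allowance at the 1% level,
    where σ̂ rescales the median singular value to the median of the
    pure-noise law.  Returns (count above threshold, singular values).
    """
    noise = np.asarray(noise, dtype=float)
    if noise.shape != (matrix.wavelengths.size,):
        raise ParameterError("noise vector must have one SD per wavelength")
    white = matrix.values / noise[None, :]
    s = np.linalg.svd(white, compute_uv=False)
    m, n = max(white.shape), min(white.shape)
    mu = _mp_median(n / m)
    sigma_hat = np.median(s) / np.sqrt(m * mu)
    edge = np.sqrt(m) + np.sqrt(n)
    # 99th percentile of the Tracy-Widom (beta=1) law is ~2.02; the largest
    # noise eigenvalue fluctuates on the scale edge * (1/sqrt(m)+1/sqrt(n))^(1/3)
    tw_allowance = 2.02 * edge * (1 / np.sqrt(m) + 1 / np.sqrt(n)) ** (1.0 / 3)
    threshold = sigma_hat * np.sqrt(edge**2 + tw_allowance)
    # numerical floor so exact low-rank data are not counted past their rank
    threshold = max(threshold, s[0] * max(white.shape) * np.finfo(float).eps)
    return int(np.sum(s > threshold)), s


# ---------------------------------------------------------------------------
# variable-projection global fit


def _basis(delays, lifetimes, irf: IRFModel) -> np.ndarray:
    return np.column_stack(
        [irf_convolved_exponential(delays, tau, irf) for tau in lifetimes]
    )


def _project(C, Y):
    """Least-squares amplitudes A (n_comp, n_wl) and residual Y − C A."""
    A, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return A, Y - C @ A


def global_fit(
    matrix: SpectralTimeMatrix,
    n: int,
    init_lifetimes,
    init_irf: IRFModel,
    noise: np.ndarray,
    fit_irf: bool = True,
    tau_bounds: tuple[float, float] = (1e-3, 1e4),
    artifact_order: int | None = None,
) -> KineticFitResult:
    """Fit n IRF-convolved exponentials globally across all wavelengths.

    Nonlinear parameters are log-lifetimes (bounded to ``tau_bounds``), the
    IRF center t0 and its width; the DADS are projected out analytically at
    every step.  With ``artifact_order`` set, a coherent-artifact model
    (Gaussian at t0 and its derivatives up to that order) joins the linear
    basis so the artifact does not bias the lifetimes.  Lifetimes whose
    ratio collapses below 1.05 trigger a :class:`DegeneracyWarning` and an
    automatic refit with n − 1 components.
    """
    init_lifetimes = np.sort(np.asarray(init_lifetimes, dtype=float))
    if n < 1 or init_lifetimes.size != n:
        raise ParameterError("need n >= 1 initial lifetimes")
    if np.any(init_lifetimes <= 0):
        raise ParameterError("initial lifetimes must be positive")
    noise = np.asarray(noise, dtype=float)
    Y = matrix.values
    delays = matrix.delays
    w = 1.0 / noise[None, :]

    params = lmfit.Parameters()
    lo, hi = np.log(tau_bounds[0]), np.log(tau_bounds[1])
    for i, tau in enumerate(init_lifetimes):
        params.add(f"logtau{i}", value=float(np.log(tau)), min=lo, max=hi)
    params.add("t0", value=init_irf.t0, min=init_irf.t0 - 1.0,
               max=init_irf.t0 + 1.0, vary=fit_irf)
    params.add("logfwhm", value=float(np.log(init_irf.fwhm)),
               min=np.log(1e-3), max=np.log(10.0), vary=fit_irf)
    if artifact_order is not None:
        # the coherent artifact is narrower than the pump-probe
        # cross-correlation in general, so it gets its own fitted width
        params.add("logart_fwhm", value=float(np.log(init_irf.fwhm)),
                   min=np.log(1e-3), max=np.log(10.0), vary=fit_irf)

    def full_basis(p, taus, irf):
        C = _basis(delays, taus, irf)
        if artifact_order is not None:
            art_irf = IRFModel(t0=irf.t0,
                               fwhm=float(np.exp(p["logart_fwhm"].value)))
            C = np.hstack([C, artifact_columns(delays, art_irf, artifact_order)])
        return C

    def residual(p):
        taus = [np.exp(p[f"logtau{i}"].value) for i in range(n)]
        irf = IRFModel(t0=p["t0"].value, fwhm=float(np.exp(p["logfwhm"].value)))
        _, R = _project(full_basis(p, taus, irf), Y)
        return (R * w).ravel()

    minres = lmfit.minimize(residual, params, method="least_squares", xtol=1e-12,
                            ftol=1e-12, gtol=1e-12)
    if not minres.success:
        raise ConvergenceError(
            "global fit did not converge", {"message": minres.message}
        )
    p = minres.params
    taus = np.array([np.exp(p[f"logtau{i}"].value) for i in range(n)])
    order = np.argsort(taus)
    taus = taus[order]
    irf = IRFModel(t0=p["t0"].value, fwhm=float(np.exp(p["logfwhm"].value)))

    if n > 1 and np.any(taus[1:] / taus[:-1] < 1.05):
        warnings.warn(
            "adjacent lifetimes collapsed (ratio < 1.05); refitting with "
            f"n = {n - 1}",
            DegeneracyWarning,
        )
        keep = np.concatenate([[True], taus[1:] / taus[:-1] >= 1.05])
        return global_fit(
            matrix, n - 1, taus[keep][: n - 1], irf, noise, fit_irf=fit_irf,
            tau_bounds=tau_bounds, artifact_order=artifact_order,
        )

    C = full_basis(p, taus, irf)
    A_full, R = _project(C, Y)
    A = A_full[:n][order]
    art = A_full[n:] if A_full.shape[0] > n else None
    chi2 = float(np.sum((R * w) ** 2))
    n_lin = A_full.shape[0]
    nfree = Y.size - (n_lin * Y.shape[1] + n + (2 if fit_irf else 0))
    dads = ComponentSpectra(
        kind="DADS",
        lifetimes=taus,
        spectra=[
            Spectrum(matrix.wavelengths.copy(), A[k], label=f"DADS tau={taus[k]:.3g} ps")
            for k in range(n)
        ],
    )
    cov = getattr(minres, "covar", None)
    return KineticFitResult(
        lifetimes=taus,
        irf=irf,
        dads=dads,
        chi2_reduced=chi2 / max(nfree, 1),
        residuals=R * w,
        covariance=cov,
        artifact_amplitudes=art,
    )


# ---------------------------------------------------------------------------
# sequential irreversible scheme 1 → 2 → … → n


def _sequential_coefficients(lifetimes: np.ndarray) -> np.ndarray:
    """B[j, l]: weight of the convolved exponential of rate k_j in species l.

    c_l(t) = Σ_{j ≤ l} B[j, l] · conv(k_j)(t); the analytic partial-fraction
    coefficients of the linear chain.  Duplicate rates make the formula
    singular and raise :class:`DegenerateRatesError`.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if np.any(lifetimes <= 0):
        raise ParameterError("lifetimes must be positive")
    k = 1.0 / lifetimes
    n = k.size
    for a in range(n):
        for b in range(a + 1, n):
            if abs(k[a] - k[b]) <= 1e-6 * max(k[a], k[b]):
                raise DegenerateRatesError(
                    f"rates {a + 1} and {b + 1} are degenerate; perturb the "
                    "lifetimes instead of relying on a limit"
                )
    B = np.zeros((n, n))
    for l in range(n):  # species index, 0-based
        prefactor = np.prod(k[:l])  # k_1 … k_{l-1}; empty product = 1
        for j in range(l + 1):
            denom = np.prod([k[m] - k[j] for m in range(l + 1) if m != j])
            B[j, l] = prefactor / denom if l > 0 else 1.0
    return B


def sequential_concentrations(
    lifetimes, irf: IRFModel, delays
) -> ConcentrationProfiles:
    """Populations of the sequential irreversible chain, IRF-convolved.

    Species 1 is created by the pump (through the IRF) and each species
    feeds the next with rate 1/τ_l; all populations decay to zero at long
    times (the last species is not a terminal sink).
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    delays = np.asarray(delays, dtype=float)
    B = _sequential_coefficients(lifetimes)
    conv = _basis(delays, lifetimes, irf)  # column j = conv(k_j)
    return ConcentrationProfiles(delays=delays, c=conv @ B)


def species_fractions(
    profiles: ConcentrationProfiles, total_floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized species fractions f_l(t) = c_l / Σ_m c_m.

    Returns (delays_kept, fractions, delays_dropped); delays whose total
    population is below ``total_floor`` (before and long after the pump)
    carry no meaningful fraction and are dropped.
    """
    total = profiles.c.sum(axis=1)
    keep = total >= total_floor
    fractions = profiles.c[keep] / total[keep, None]
    return profiles.delays[keep], fractions, profiles.delays[~keep]


def dads_to_eads(dads: ComponentSpectra, lifetimes=None) -> ComponentSpectra:
    """Convert DADS of a parallel decomposition into EADS of the sequential
    scheme with the same lifetimes.

    Both representations reproduce the identical fitted surface:
    Σ_l EADS_l·c_l(t) = Σ_k DADS_k·conv(k_k)(t).  Expanding c_l in the
    convolved-exponential basis gives the triangular system
    DADS_j = Σ_l B[j, l]·EADS_l, solved exactly.  The first EADS always
    equals the sum of all DADS (at t = 0⁺ only species 1 is populated).
    """
    if dads.kind != "DADS":
        raise ParameterError("input spectra must be DADS")
    lifetimes = dads.lifetimes if lifetimes is None else np.asarray(lifetimes, float)
    B = _sequential_coefficients(lifetimes)
    D = dads.as_array()  # (n, n_wl)
    from scipy.linalg import solve_triangular

    E = solve_triangular(B, D, lower=False)
    return ComponentSpectra(
        kind="EADS",
        lifetimes=lifetimes.copy(),
        spectra=[
            Spectrum(dads.wavelengths.copy(), E[k],
                     label=f"EADS tau={lifetimes[k]:.3g} ps")
            for k in range(E.shape[0])
        ],
    )
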