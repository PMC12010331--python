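"""Synthetic transient-absorption matrices and fluorescence decays.

The generator reproduces the statistical structure that the downstream
analysis assumes: multiexponential kinetics convolved with a Gaussian IRF,
band-structured component spectra with negative (ground-state bleach) and
positive (excited-state absorption) features, a wavelength-dependent time
zero from supercontinuum chirp, a coherent artifact localized at time zero,
and additive detector noise (Gaussian for the CCD-detected ΔA, Poisson for
photon-counting fluorescence).  Everything is deterministic given the seed.

The ``fcc_like_preset`` emulates a flavocytochrome pump–probe experiment:
probe 290–1000 nm, 20 fs steps through the IRF window with logarithmic
sampling out to 1 ns, two kinetic components near 0.4 ps (internal
conversion) and 4 ps (vibrational cooling), and a ~0.10 ps IRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import SpectralTimeMatrix, Spectrum
from .exceptions import ParameterError
from .global_kinetics import (
    IRFModel,
    irf_convolved_exponential,
    sequential_concentrations,
)

__all__ = [
    "KineticComponentSpec",
    "SimulationSpec",
    "FluorescenceDecay",
    "make_time_grid",
    "gaussian_band_spectrum",
    "simulate_ta",
    "simulate_fluorescence",
    "fcc_like_preset",
    "default_wavelengths",
    "default_delays",
]

_GAUSS_FWHM = 4.0 * np.log(2.0)


@dataclass
class KineticComponentSpec:
    """Ground truth for one kinetic component: lifetime and its amplitude
    spectrum (a DADS for the parallel model, a species spectrum for the
    sequential one)."""

    lifetime: float
    spectrum: Spectrum

    def __post_init__(self):
        if self.lifetime <= 0:
            raise ParameterError("component lifetime must be positive")


@dataclass
class SimulationSpec:
    """Full description of a synthetic pump–probe measurement."""

    components: list[KineticComponentSpec]
    irf: IRFModel = field(default_factory=IRFModel)
    model: str = "parallel"  # or "sequential"
    chirp_poly: tuple[float, ...] = (0.0,)  # t0(u), u = (λ−290)/710
    artifact_amp: float = 0.0  # mOD
    artifact_fwhm: float = 0.05  # ps
    noise_sd: float = 0.0  # mOD
    seed: int = 0

    def __post_init__(self):
        if not self.components:
            raise ParameterError("at least one kinetic component required")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.model not in ("parallel", "sequential"):
            raise ParameterError("model must be 'parallel' or 'sequential'")

    def chirp_t0(self, wavelengths: np.ndarray) -> np.ndarray:
        u = (np.asarray(wavelengths, float) - 290.0) / 710.0
        return np.polyval(self.chirp_poly[::-1], u)


@dataclass
class FluorescenceDecay:
    """A time-resolved fluorescence trace with its instrument response.

    ``irf`` is either a Gaussian :class:`IRFModel` or a measured trace on the
    same delay axis.  ``expected`` (if present) carries the noise-free model
    counts the trace was Poisson-sampled from.
    """

    delays: np.ndarray
    counts: np.ndarray
    irf: IRFModel | np.ndarray
    acquisition: str = "upconversion"  # or "tcspc"
    resolution_ps: float = 0.15
    expected: np.ndarray | None = None

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.delays.shape:
            raise ParameterError("counts and delays must have equal length")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be nonnegative")
        if isinstance(self.irf, np.ndarray) and self.irf.shape != self.delays.shape:
            raise ParameterError("trace IRF must share the delay axis")


# ---------------------------------------------------------------------------


def make_time_grid(
    step_fs: float, irf_window_ps: float, t_max_ps: float, points_per_decade: int
) -> np.ndarray:
    """Pump–probe delay axis: linear ``step_fs`` steps across
    [−irf_window, +irf_window], then logarithmic sampling
    (``points_per_decade``) out to ``t_max_ps``.  Strictly increasing."""
    if step_fs <= 0 or irf_window_ps <= 0 or points_per_decade < 1:
        raise ParameterError("grid parameters must be positive")
    if t_max_ps < irf_window_ps:
        raise ParameterError("t_max_ps must reach at least the IRF window edge")
    step = step_fs * 1e-3
    nhalf = int(round(irf_window_ps / step))
    linear = np.arange(-nhalf, nhalf + 1) * step
    n_log = int(np.floor(points_per_decade * np.log10(t_max_ps / irf_window_ps) + 1e-9))
    log_part = irf_window_ps * 10 ** (np.arange(1, n_log + 1) / points_per_decade)
    grid = np.concatenate([linear, log_part])
    grid = np.unique(grid)
    return grid


def gaussian_band_spectrum(
    wavelengths, bands: list[tuple[float, float, float]], label: str = ""
) -> Spectrum:
    """Sum of Gaussian bands (center nm, FWHM nm, amplitude mOD); negative
    amplitudes model ground-state bleaches."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.zeros_like(wavelengths)
    for center, fwhm, amp in bands:
        if fwhm <= 0:
            raise ParameterError("band FWHM must be positive")
        values += amp * np.exp(-_GAUSS_FWHM * ((wavelengths - center) / fwhm) ** 2)
    return Spectrum(wavelengths, values, label=label)


def _kinetic_profiles(spec: SimulationSpec, delays, irf: IRFModel) -> np.ndarray:
    taus = [c.lifetime for c in spec.components]
    if spec.model == "parallel":
        return np.column_stack(
            [irf_convolved_exponential(delays, tau, irf) for tau in taus]
        )
    return sequential_concentrations(taus, irf, delays).c


def simulate_ta(
    spec: SimulationSpec, wavelengths, delays
) -> SpectralTimeMatrix:
    """Forward-model a ΔA(λ, t) matrix.

    ΔA = Σ_k S_k(λ)·c_k(t − t0(λ)) + artifact + noise, with c_k the
    IRF-convolved kinetics (parallel DADS sum or sequential populations),
    t0(λ) the chirp polynomial, the coherent artifact a Gaussian in time at
    t0(λ), and i.i.d. Gaussian noise from the stated seed.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    delays = np.asarray(delays, dtype=float)
    S = np.vstack(
        [
            np.interp(wavelengths, c.spectrum.wavelengths, c.spectrum.values)
            if c.spectrum.wavelengths.shape != wavelengths.shape
            or not np.allclose(c.spectrum.wavelengths, wavelengths)
            else c.spectrum.values
            for c in spec.components
        ]
    )  # (n_comp, n_wl)
    t0 = spec.chirp_t0(wavelengths)
    values = np.empty((delays.size, wavelengths.size))
    art_sigma = spec.artifact_fwhm / (2 * np.sqrt(2 * np.log(2)))
    for i, (t0_i, s_col) in enumerate(zip(t0, S.T)):
        irf_i = IRFModel(t0=spec.irf.t0 + t0_i, fwhm=spec.irf.fwhm)
        C = _kinetic_profiles(spec, delays, irf_i)  # (n_t, n_comp)
        col = C @ s_col
        if spec.artifact_amp != 0.0:
            col = col + spec.artifact_amp * np.exp(
                -0.5 * ((delays - spec.irf.t0 - t0_i) / art_sigma) ** 2
            )
        values[:, i] = col
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return SpectralTimeMatrix(
        wavelengths, delays, values, label=f"synthetic {spec.model}"
    )


def simulate_fluorescence(
    lifetimes,
    amplitudes,
    irf: IRFModel,
    delays,
    total_counts: int,
    seed: int = 0,
    sample: bool = True,
    acquisition: str = "upconversion",
) -> FluorescenceDecay:
    """Multiexponential fluorescence decay with Poisson counting noise.

    Expected counts per bin are proportional to Σ_i A_i·conv(τ_i)(t) and
    scaled so the total equals ``total_counts``; with ``sample=True`` each
    bin is then Poisson-drawn from the stated seed.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if np.any(amplitudes < 0):
        raise ParameterError("emission amplitudes must be nonnegative")
    if not np.any(amplitudes > 0):
        raise ParameterError("at least one amplitude must be positive")
    if total_counts <= 0:
        raise ParameterError("total_counts must be positive")
    model = np.zeros_like(delays)
    for tau, amp in zip(lifetimes, amplitudes):
        model += amp * irf_convolved_exponential(delays, tau, irf)
    expected = model * (total_counts / model.sum())
    if sample:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected.copy()
    return FluorescenceDecay(
        delays=delays,
        counts=counts,
        irf=irf,
        acquisition=acquisition,
        resolution_ps=irf.fwhm,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# the flavocytochrome-like emulation preset


def default_wavelengths(n: int = 80) -> np.ndarray:
    return np.linspace(290.0, 1000.0, n)


def default_delays() -> np.ndarray:
    """20 fs steps across ±0.5 ps, then 20 points/decade out to 1 ns."""
    return make_time_grid(20.0, 0.5, 1000.0, 20)


def fcc_like_preset(
    lifetimes: tuple[float, float] = (0.4, 4.3),
    irf_fwhm: float = 0.10,
    noise_frac: float = 0.02,
    chirp: bool = True,
    artifact: bool = True,
    seed: int = 0,
    n_wavelengths: int = 80,
) -> SimulationSpec:
    """Two-component parallel model emulating a flavocytochrome TA dataset.

    Component 1 (fast, internal conversion): a narrow Soret-region bleach
    near 410–415 nm with an adjacent excited-state absorption and a broad
    positive band around 700 nm.  Component 2 (slow, vibrational cooling): a
    410/420 nm negative/positive pair plus the weaker 525/550/575 nm
    negative/positive/positive structure of a hot ground state.
    ``noise_frac`` scales the additive Gaussian noise to the clean-signal
    peak |ΔA|.
    """
    wl = default_wavelengths(n_wavelengths)
    comp1 = KineticComponentSpec(
        lifetime=lifetimes[0],
        spectrum=gaussian_band_spectrum(
            wl, [(410.0, 22.0, -6.0), (420.0, 28.0, 3.0), (700.0, 150.0, 2.5)],
            label="internal conversion",
        ),
    )
    comp2 = KineticComponentSpec(
        lifetime=lifetimes[1],
        spectrum=gaussian_band_spectrum(
            wl,
            [(410.0, 20.0, -4.0), (422.0, 25.0, 2.0), (525.0, 30.0, -1.5),
             (550.0, 30.0, 1.2), (575.0, 35.0, 1.2)],
            label="vibrational cooling",
        ),
    )
    spec = SimulationSpec(
        components=[comp1, comp2],
        irf=IRFModel(t0=0.0, fwhm=irf_fwhm),
        model="parallel",
        chirp_poly=(-0.08, 0.20, -0.05, 0.03) if chirp else (0.0,),
        artifact_amp=1.0 if artifact else 0.0,
        artifact_fwhm=0.05,
        noise_sd=0.0,
        seed=seed,
    )
    # noise quoted relative to the measured signal peak: evaluate the clean
    # (noise- and artifact-free) matrix once and scale
    clean = SimulationSpec(
        components=spec.components, irf=spec.irf, model=spec.model,
        chirp_poly=spec.chirp_poly, artifact_amp=0.0, noise_sd=0.0, seed=seed,
    )
    peak = float(
        np.abs(simulate_ta(clean, wl, default_delays()).values).max()
    )
    spec.noise_sd = noise_frac * peak
    return spec
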