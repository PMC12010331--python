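import numpy as np
import pytest

from taglobal.core_io import AnalysisConfig, SpectralTimeMatrix
from taglobal.global_kinetics import IRFModel
from taglobal import synthetic_data as sd


@pytest.fixture
def small_matrix():
    """A tiny well-formed matrix for I/O and slicing tests."""
    wl = np.array([300.0, 400.0, 500.0])
    t = np.array([-1.0, 0.0, 1.0, 10.0])
    vals = np.arange(12, dtype=float).reshape(4, 3)
    return SpectralTimeMatrix(wl, t, vals, pump_nm=400.0, label="toy")


def numeric_convolution(t, tau, irf: IRFModel, dt=None):
    """Brute-force oracle: Gaussian IRF (x) exponential by trapezoid sums.

    Integrates over the exponential's own variable, c(t) = ∫_0^∞ e^(−u/τ)
    g(t − u) du, so the Heaviside kink sits exactly at the integration
    boundary.  Independent of the closed-form implementation.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    s = irf.sigma
    if dt is None:
        dt = min(s, tau) / 400.0
    u_max = 40.0 * tau + 10.0 * s
    u = np.arange(0.0, u_max, dt)
    decay = np.exp(-u / tau)
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        x = (ti - u - irf.t0) / s
        gauss = np.exp(-0.5 * x**2) / (s * np.sqrt(2 * np.pi))
        out[i] = np.trapezoid(decay * gauss, u)
    return out if out.size > 1 else float(out[0])


@pytest.fixture(scope="session")
def fcc_seed1():
    """The two-component emulation preset (0.4 / 4.3 ps) and its matrix."""
    spec = sd.fcc_like_preset(lifetimes=(0.4, 4.3), seed=1)
    matrix = sd.simulate_ta(
        spec, sd.default_wavelengths(), sd.default_delays()
    )
    return spec, matrix


@pytest.fixture(scope="session")
def lda_seed1(fcc_seed1):
    """Full LDA pipeline result on the seed-1 preset (shared: it is the
    most expensive fixture in the suite)."""
    from taglobal import pipelines

    _, matrix = fcc_seed1
    return pipelines.lda_pipeline(matrix, AnalysisConfig())
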