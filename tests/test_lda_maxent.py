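import numpy as np
import pytest

from taglobal import lda_maxent as lda
from taglobal import preprocess as pp
from taglobal import synthetic_data as sd
from taglobal.core_io import SpectralTimeMatrix
from taglobal.exceptions import NoComponentError, ParameterError
from taglobal.global_kinetics import IRFModel, irf_convolved_exponential


SHARP = IRFModel(0.0, 1e-5)


class TestLifetimeGrid:
    @pytest.mark.parametrize("tmin,tmax,ppd,expected", [
        (1.0, 10.0, 1, [1.0, 10.0]),
        (1.0, 100.0, 1, [1.0, 10.0, 100.0]),
    ])
    def test_small_grids(self, tmin, tmax, ppd, expected):
        grid = lda.build_lifetime_grid(tmin, tmax, ppd)
        np.testing.assert_allclose(grid.lifetimes, expected)

    def test_default_grid_has_95_points(self):
        # round(20 * log10(1000/0.02)) + 1
        grid = lda.build_lifetime_grid(0.02, 1000.0, 20)
        assert len(grid) == 95
        assert grid.lifetimes[0] == pytest.approx(0.02)
        assert grid.lifetimes[-1] == pytest.approx(1000.0)

    def test_log_uniform_enforced(self):
        with pytest.raises(ParameterError):
            lda.LifetimeGrid(np.array([1.0, 2.0, 10.0]))

    def test_invalid_bounds(self):
        with pytest.raises(ParameterError):
            lda.build_lifetime_grid(10.0, 1.0, 20)


class TestDesignMatrix:
    def test_sharp_irf_value_at_tau(self):
        grid = lda.LifetimeGrid(np.array([0.5]))
        M = lda.design_matrix(np.array([0.5]), grid, SHARP)
        assert M[0, 0] == pytest.approx(np.exp(-1), abs=1e-9)

    def test_entries_bounded(self):
        grid = lda.build_lifetime_grid(0.02, 1000, 10)
        t = sd.make_time_grid(20, 0.5, 1000, 10)
        M = lda.design_matrix(t, grid, IRFModel(0.0, 0.1))
        assert M.min() >= -1e-9 and M.max() <= 1 + 1e-9

    def test_slow_component_barely_decayed(self):
        grid = lda.LifetimeGrid(np.array([1000.0]))
        M = lda.design_matrix(np.array([1.0]), grid, SHARP)
        assert M[0, 0] == pytest.approx(np.exp(-0.001), rel=1e-6)


def _column_matrix(delays, values):
    return SpectralTimeMatrix(np.array([500.0]), delays,
                              np.asarray(values, float)[:, None])


class TestMaxentFit:
    def test_zero_data_gives_zero_amplitudes(self):
        t = sd.make_time_grid(50, 0.5, 100, 10)
        m = _column_matrix(t, np.zeros(t.size))
        grid = lda.build_lifetime_grid(0.05, 50, 10)
        fit = lda.maxent_fit(m, grid, IRFModel(0.0, 0.1), np.array([0.1]), 1.0)
        np.testing.assert_allclose(fit.amplitudes, 0.0, atol=1e-12)

    def test_huge_alpha_kills_amplitudes(self):
        t = sd.make_time_grid(50, 0.5, 100, 10)
        y = 3.0 * irf_convolved_exponential(t, 1.0, IRFModel(0.0, 0.1))
        m = _column_matrix(t, y)
        grid = lda.build_lifetime_grid(0.05, 50, 10)
        noise = np.array([0.1])
        fit = lda.maxent_fit(m, grid, IRFModel(0.0, 0.1), noise, 1e9)
        assert np.abs(fit.amplitudes).max() < 1e-3
        assert fit.chi2 == pytest.approx(np.sum((y / 0.1) ** 2), rel=1e-3)

    def test_noiseless_single_exponential_mass_concentrates(self):
        """A noiseless on-grid exponential localizes at its lifetime: the
        amplitude mass within one grid step of the truth beats the
        brute-force ridge solution on the same basis (the exponential basis
        is so collinear that ridge itself only reaches ~60%)."""
        grid = lda.build_lifetime_grid(0.05, 50, 10)
        tau0 = grid.lifetimes[15]
        irf = IRFModel(0.0, 0.1)
        t = sd.make_time_grid(20, 0.5, 200, 20)
        y = 5.0 * irf_convolved_exponential(t, tau0, irf)
        m = _column_matrix(t, y)
        fit = lda.maxent_fit(m, grid, irf, np.array([0.01]), 1e-3)
        a = np.abs(fit.amplitudes[0])
        assert abs(int(np.argmax(a)) - 15) <= 1
        M = lda.design_matrix(t, grid, irf)
        ridge = np.abs(np.linalg.solve(
            M.T @ M + 1e-6 * np.eye(len(grid)), M.T @ y
        ))
        maxent_frac = a[14:17].sum() / a.sum()
        ridge_frac = ridge[14:17].sum() / ridge.sum()
        assert maxent_frac >= ridge_frac
        assert maxent_frac >= 0.80

    def test_ridge_oracle_equivalence_on_fitted_signal(self):
        """With matched penalty scale, the maxent fitted surface agrees with
        a direct ridge solve within 1% rms on noiseless data."""
        grid = lda.build_lifetime_grid(0.05, 50, 10)
        irf = IRFModel(0.0, 0.1)
        t = sd.make_time_grid(40, 0.5, 100, 10)
        y = 4.0 * irf_convolved_exponential(t, 1.2, irf) \
            - 1.5 * irf_convolved_exponential(t, 8.0, irf)
        m = _column_matrix(t, y)
        sigma, alpha = 0.05, 1e-2
        prior = lda._prior_scale(m.values, 0.01)[0]
        fit = lda.maxent_fit(m, grid, irf, np.array([sigma]), alpha)
        M = lda.design_matrix(t, grid, irf)
        lam = alpha * sigma**2 / (4 * prior)  # entropy ~ a^2/(4m) near zero
        a_ridge = np.linalg.solve(M.T @ M + lam * np.eye(len(grid)), M.T @ y)
        rms = np.sqrt(np.mean((M @ fit.amplitudes[0] - M @ a_ridge) ** 2))
        assert rms <= 0.01 * np.sqrt(np.mean(y**2))


@pytest.fixture(scope="module")
def scan():
    spec = sd.fcc_like_preset(seed=8, chirp=False, artifact=False,
                              n_wavelengths=12)
    wl = sd.default_wavelengths(12)
    t = sd.make_time_grid(40, 0.5, 500, 10)
    m = sd.simulate_ta(spec, wl, t)
    noise = np.full(12, spec.noise_sd)
    grid = lda.build_lifetime_grid(0.02, 1000, 10)
    alphas = lda.default_alphas(m, grid, IRFModel(0.0, 0.1), noise,
                                n_alphas=15)
    return lda.l_curve_select(m, grid, IRFModel(0.0, 0.1), noise, alphas)


class TestLCurve:
    def test_chi2_nondecreasing(self, scan):
        _, table = scan
        dchi = np.diff(table["chi2"])
        assert np.all(dchi >= -1e-6 * table["chi2"][:-1])

    def test_entropy_nonincreasing(self, scan):
        _, table = scan
        dR = np.diff(table["entropy"])
        assert np.all(dR <= 1e-6 * table["entropy"][:-1])

    def test_corner_strictly_inside_scan(self, scan):
        alpha, table = scan
        assert table["alpha"][0] < alpha < table["alpha"][-1]

    def test_too_few_alphas_rejected(self, small_matrix):
        with pytest.raises(ParameterError):
            lda.l_curve_select(small_matrix,
                               lda.build_lifetime_grid(0.1, 10, 5),
                               IRFModel(), np.ones(3), [1.0, 2.0])


class TestDynamicalContent:
    @staticmethod
    def _map(amps):
        amps = np.asarray(amps, float)
        grid = lda.LifetimeGrid(np.geomspace(0.1, 10, amps.shape[1]))
        wl = np.linspace(300, 700, amps.shape[0])
        return lda.LifetimeDensityMap(grid, wl, amps, alpha=1.0, chi2=0.0)

    def test_zero_map(self):
        d = lda.dynamical_content(self._map(np.zeros((3, 5))))
        np.testing.assert_array_equal(d.d, 0.0)

    def test_pythagoras(self):
        amps = np.zeros((2, 3))
        amps[:, 1] = [3.0, 4.0]
        d = lda.dynamical_content(self._map(amps))
        assert d.d[1] == pytest.approx(5.0)

    def test_absolute_homogeneity(self):
        rng = np.random.default_rng(1)
        amps = rng.normal(size=(4, 6))
        base = lda.dynamical_content(self._map(amps)).d
        scaled = lda.dynamical_content(self._map(-2.5 * amps)).d
        np.testing.assert_allclose(scaled, 2.5 * base)

    def test_invariant_under_wavelength_permutation(self):
        rng = np.random.default_rng(2)
        amps = rng.normal(size=(5, 6))
        base = lda.dynamical_content(self._map(amps)).d
        perm = lda.dynamical_content(self._map(amps[::-1])).d
        np.testing.assert_allclose(perm, base)


class TestFindComponents:
    @staticmethod
    def _content(d):
        d = np.asarray(d, float)
        grid = lda.LifetimeGrid(np.geomspace(0.01, 100, d.size))
        return lda.DynamicalContent(grid, d)

    def test_single_gaussian_peak(self):
        tau = np.geomspace(0.01, 100, 81)
        d = np.exp(-0.5 * ((np.log(tau) - np.log(2.0)) / 0.5) ** 2)
        windows = lda.find_components(self._content(d), floor_ps=0.15)
        assert len(windows) == 1
        w = windows[0]
        assert w.lo < 2.0 < w.hi
        assert w.peak_lifetime == pytest.approx(2.0, rel=0.1)

    def test_subfloor_peak_excluded(self):
        tau = np.geomspace(0.01, 100, 81)
        d = (2.0 * np.exp(-0.5 * ((np.log(tau) - np.log(0.05)) / 0.3) ** 2)
             + np.exp(-0.5 * ((np.log(tau) - np.log(4.0)) / 0.3) ** 2))
        windows = lda.find_components(self._content(d), floor_ps=0.15)
        assert len(windows) == 1
        assert windows[0].peak_lifetime == pytest.approx(4.0, rel=0.12)

    def test_two_separated_peaks_have_disjoint_windows(self):
        tau = np.geomspace(0.01, 100, 81)
        d = (np.exp(-0.5 * ((np.log(tau) - np.log(0.5)) / 0.25) ** 2)
             + np.exp(-0.5 * ((np.log(tau) - np.log(20.0)) / 0.25) ** 2))
        w1, w2 = lda.find_components(self._content(d), floor_ps=0.05)
        assert w1.hi < w2.lo
        assert w1.peak_lifetime == pytest.approx(0.5, rel=0.1)
        assert w2.peak_lifetime == pytest.approx(20.0, rel=0.1)

    def test_two_equal_overlapping_peaks_share_valley_boundary(self):
        # broad enough that the half-max regions meet: the shared boundary
        # is the valley between the peaks
        tau = np.geomspace(0.01, 100, 81)
        d = (np.exp(-0.5 * ((np.log(tau) - np.log(0.5)) / 1.2) ** 2)
             + np.exp(-0.5 * ((np.log(tau) - np.log(20.0)) / 1.2) ** 2))
        w1, w2 = lda.find_components(self._content(d), floor_ps=0.05)
        valley = np.sqrt(0.5 * 20.0)
        assert w1.hi == pytest.approx(valley, rel=0.15)
        assert w2.lo == pytest.approx(valley, rel=0.15)

    def test_no_peak_above_floor_raises(self):
        tau = np.geomspace(0.01, 100, 41)
        d = np.exp(-0.5 * ((np.log(tau) - np.log(0.05)) / 0.2) ** 2)
        with pytest.raises(NoComponentError):
            lda.find_components(self._content(d), floor_ps=0.15)


class TestExtractDads:
    @staticmethod
    def _map(seed=0, n_wl=4, n_tau=12):
        rng = np.random.default_rng(seed)
        grid = lda.LifetimeGrid(np.geomspace(0.1, 100, n_tau))
        return lda.LifetimeDensityMap(
            grid, np.linspace(300, 700, n_wl),
            rng.normal(size=(n_wl, n_tau)), alpha=1.0, chi2=0.0,
        )

    def test_whole_grid_window_gives_row_sums(self):
        dm = self._map()
        w = lda.ComponentWindow(1.0, 0.05, 200.0)
        dads = lda.extract_dads(dm, [w])
        np.testing.assert_allclose(dads.spectra[0].values,
                                   dm.amplitudes.sum(axis=1))

    def test_partition_additivity(self):
        dm = self._map(seed=3)
        mid = 3.0
        w1 = lda.ComponentWindow(1.0, 0.05, mid)
        w2 = lda.ComponentWindow(10.0, mid + 1e-9, 200.0)
        dads = lda.extract_dads(dm, [w1, w2])
        total = dads.spectra[0].values + dads.spectra[1].values
        np.testing.assert_allclose(total, dm.amplitudes.sum(axis=1),
                                   atol=1e-12)

    def test_recovered_dads_match_generator_spectra(self, fcc_seed1,
                                                    lda_seed1):
        spec, _ = fcc_seed1
        dads = lda_seed1["dads"]
        assert len(dads.spectra) == 2
        for rec, comp in zip(dads.spectra, spec.components):
            cos = np.dot(rec.values, comp.spectrum.values) / (
                np.linalg.norm(rec.values)
                * np.linalg.norm(comp.spectrum.values)
            )
            assert cos >= 0.95
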