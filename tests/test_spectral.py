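"""Detrending, periodogram, detector-bias correction, and the χ² criterion."""

import numpy as np
import pytest

from circaclock.spectral import (
    DetrendKernel,
    SpectrumSet,
    chi_squared,
    detector_bias_terms,
    detrend,
    model_spectrum,
    periodogram,
    spectrum_from_cells,
)
from circaclock.ssa import GridSeries, uniform_grid

from conftest import birth_death_network


def _series(values, T=None):
    values = np.asarray(values, float)
    L = len(values)
    T = T if T is not None else L * 0.5
    return GridSeries(t=uniform_grid(L, T), values=values, species="g_p")


class TestDetrend:
    def test_constant_series_maps_to_zero(self):
        out = detrend(_series(np.full(200, 7.0)), DetrendKernel(49))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_linear_ramp_interior_residual_near_zero(self):
        out = detrend(_series(np.linspace(0, 10, 300)), DetrendKernel(49))
        interior = out.values[30:-30]
        assert np.abs(interior).max() < 1e-10

    def test_attenuation_matches_transfer_function(self):
        """A sinusoid far above the window's cutoff passes; far below it is
        removed; interior gains match the analytic moving-average response
        |1 - H_MA(f)|."""
        L, w = 2048, 49
        kern = DetrendKernel(w)
        for period_pts in (16, 1024):
            f = 1.0 / period_pts
            x = np.sin(2 * np.pi * f * np.arange(L))
            y = kern.apply(x)[300:-300]
            gain = np.sqrt(np.mean(y ** 2) / 0.5)
            H = np.sin(np.pi * f * w) / (w * np.sin(np.pi * f))
            expected = abs(1 - H)
            assert gain == pytest.approx(expected, abs=0.02), period_pts
        # long periods strongly attenuated, short ones retained
        assert kern.apply(np.sin(2 * np.pi * np.arange(L) / 1024))[300:-300].std() < 0.15
        assert kern.apply(np.sin(2 * np.pi * np.arange(L) / 16))[300:-300].std() > 0.6

    def test_window_must_be_shorter_than_series(self):
        with pytest.raises(ValueError):
            DetrendKernel(49).apply(np.zeros(20))
        with pytest.raises(ValueError):
            DetrendKernel(48)  # even windows have no center


class TestPeriodogram:
    def test_zero_series_zero_power(self):
        assert np.all(periodogram(_series(np.zeros(64))) == 0.0)

    def test_grid_frequency_sinusoid_single_bin(self):
        L = 128
        x = np.sin(2 * np.pi * 8 * np.arange(L) / L)
        Q = periodogram(_series(x))
        assert np.argmax(Q) == 7  # bin l = 8 (1-based l, array 0-based)
        others = np.delete(Q, 7)
        assert np.all(others < 1e-20 * Q[7] + 1e-12)

    def test_parseval_normalization(self):
        """Sum of two-sided powers equals the sum of squares: with the
        |X_l|^2/L one-sided convention, sum(|rfft|^2 contributions)/L ==
        sum(x^2)."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=256)
        X = np.fft.rfft(x)
        two_sided = (np.abs(X[0]) ** 2 + np.abs(X[-1]) ** 2
                     + 2 * np.sum(np.abs(X[1:-1]) ** 2)) / len(x)
        assert two_sided == pytest.approx(np.sum(x ** 2), rel=1e-10)
        # and the module's Q matches |X|^2/L on the positive bins
        Q = periodogram(_series(x))
        np.testing.assert_allclose(Q, np.abs(X[1:129]) ** 2 / 256, rtol=1e-12)

    def test_six_hour_day_produces_256_frequencies(self):
        """The 6 h-day acquisition: L = 512 half-hour samples over 256 h give
        positive frequencies l/T, l = 1..256."""
        L, T = 512, 256.0
        spec = spectrum_from_cells([np.random.default_rng(0).normal(size=L)],
                                   T=T)
        assert spec.n_frequencies == 256
        assert spec.f[0] == pytest.approx(1 / 256.0)
        assert spec.f[-1] == pytest.approx(1.0)


class TestDetectorBias:
    def test_zero_noise_zero_terms(self):
        rng = np.random.default_rng(0)
        cells = [rng.normal(size=128) for _ in range(10)]
        spec = spectrum_from_cells(cells, T=64.0, sigma_eps2=0.0)
        assert np.all(spec.Q_bias == 0.0)
        assert np.all(spec.var_detector == 0.0)

    def test_pure_noise_spectrum_centered_on_zero_after_correction(self):
        """Cells with no biological signal: the corrected average
        periodogram <Q> - Q_bias is centered on zero across frequencies."""
        rng = np.random.default_rng(42)
        L, K, s2 = 96, 2000, 4.0
        kern = DetrendKernel(25)
        cells = [rng.normal(0.0, np.sqrt(s2), size=L) for _ in range(K)]
        spec = spectrum_from_cells(cells, T=48.0, kernel=kern, sigma_eps2=s2)
        corrected = spec.corrected_Q()
        # uncorrected bias is ~s2*gamma/L ~ O(s2); corrected mean ~ 0
        assert np.abs(np.mean(corrected)) < 0.05 * np.mean(spec.Q_avg)
        # bias correction removes >= 90% of the mean bias
        assert np.mean(np.abs(corrected)) < 0.1 * np.mean(spec.Q_avg)

    def test_no_detrend_limit_recovers_classical_white_noise_bias(self):
        """Without detrending the response reduces to the classical flat
        white-noise periodogram level: gamma_Q = L at every bin (so
        Q_bias = sigma_eps2), and the empirical white-noise spectrum sits at
        sigma_eps2."""
        L = 64
        # operator response of "no detrending" (residual = identity):
        # gamma_Q(l) = sum_k |F_lk|^2 = L, beta nearly vanishes off-DC
        F = np.fft.fft(np.eye(L), axis=0)[1: L // 2 + 1]
        gamma = np.sum(np.abs(F) ** 2, axis=1)
        np.testing.assert_allclose(gamma, L, rtol=1e-12)
        rng = np.random.default_rng(3)
        s2 = 9.0
        cells = [rng.normal(0, np.sqrt(s2), size=L) for _ in range(4000)]
        spec = spectrum_from_cells(cells, T=32.0, sigma_eps2=0.0,
                                   already_detrended=True)
        # E[Q(f_l)] = sigma^2 = (sigma_eps2/L) * gamma under this convention
        assert np.mean(spec.Q_avg) == pytest.approx(s2, rel=0.05)

    def test_negative_sigma_rejected(self):
        rng = np.random.default_rng(0)
        spec = spectrum_from_cells([rng.normal(size=96) for _ in range(3)],
                                   T=48.0)
        spec.sigma_eps2 = -1.0
        with pytest.raises(ValueError):
            detector_bias_terms(spec)

    def test_variance_flooring_keeps_corrected_variance_positive(self):
        rng = np.random.default_rng(9)
        cells = [rng.normal(0, 2.0, size=64) for _ in range(30)]
        spec = spectrum_from_cells(cells, T=32.0, sigma_eps2=4.0)
        assert np.all(spec.var_corrected > 0)


class TestChiSquared:
    def _spec_pair(self, resid, var):
        f = np.array([1 / 24.0])
        data = SpectrumSet(f=f, Q_avg=np.array([resid]), R_avg=np.zeros(1, complex),
                           var_total=np.array([var]), K_cells=10, L_points=4,
                           T_dur=24.0)
        data.Q_bias = np.zeros(1)
        data.var_corrected = np.array([var])
        model = SpectrumSet(f=f, Q_avg=np.zeros(1), R_avg=np.zeros(1, complex),
                            var_total=np.zeros(1), K_cells=10, L_points=4,
                            T_dur=24.0)
        return model, data

    def test_equal_spectra_give_zero(self):
        model, data = self._spec_pair(0.0, 2.0)
        chi2, loglik = chi_squared(model, data)
        assert chi2 == 0.0
        assert loglik == 0.0

    def test_single_term_formula(self):
        model, data = self._spec_pair(3.0, 4.0)
        chi2, _ = chi_squared(model, data)
        assert chi2 == pytest.approx(9.0 / 4.0)
        chi2_t, loglik_t = chi_squared(model, data, temperature=2.0)
        assert loglik_t == pytest.approx(-chi2 / 4.0)

    def test_grid_mismatch_rejected(self):
        model, data = self._spec_pair(1.0, 1.0)
        model.f = model.f * 2
        with pytest.raises(ValueError, match="grids"):
            chi_squared(model, data)

    def test_pooled_experiments_add(self):
        """Independent experiments multiply likelihoods: total χ² is the sum,
        and the four-experiment frequency budget is 240+256+201+256 = 953."""
        assert 240 + 256 + 201 + 256 == 953
        model, data = self._spec_pair(2.0, 1.0)
        chi2_one, _ = chi_squared(model, data)
        assert chi2_one * 4 == pytest.approx(16.0)

    def test_invariance_to_cell_and_frequency_order(self):
        rng = np.random.default_rng(17)
        cells = [rng.normal(size=64) + 5 for _ in range(12)]
        spec1 = spectrum_from_cells(cells, T=32.0, sigma_eps2=0.5)
        spec2 = spectrum_from_cells(cells[::-1], T=32.0, sigma_eps2=0.5)
        model = spectrum_from_cells([rng.normal(size=64) for _ in range(6)],
                                    T=32.0)
        c1, _ = chi_squared(model, spec1)
        c2, _ = chi_squared(model, spec2)
        assert c1 == pytest.approx(c2, rel=1e-12)


class TestModelSpectrum:
    def test_known_oscillation_peaks_at_its_period(self):
        """A high-count birth-death process driven by a square-wave light
        with a 24 h day shows its driving period as the spectral peak."""
        from circaclock.network import LightProgram, Reaction, ReactionNetwork, Species
        net = ReactionNetwork(
            [Species("A")],
            [Reaction("b0", products={"A": 1}, rate=2000.0),
             Reaction("bL", products={"A": 1}, rate=8000.0, uses_light=True),
             Reaction("d", reactants={"A": 1}, rate=1.0)],
            light=LightProgram(t_LD=12.0, duration=240.0),
            initial_counts={"A": 2000},
        )
        spec = model_spectrum(net, n_traj=16, L=480, T=240.0, seed=4,
                              species="A")
        assert spec.peak_period() == pytest.approx(24.0, abs=1.0)

    def test_mean_spectrum_stable_in_n_traj(self, clock_dark):
        s1 = model_spectrum(clock_dark, 12, 96, 48.0, seed=1)
        s2 = model_spectrum(clock_dark, 24, 96, 48.0, seed=2)
        # doubling n_traj leaves the mean spectrum unchanged within MC error
        num = np.abs(s1.Q_avg - s2.Q_avg)
        scale = np.sqrt(s1.var_total * s1.K_cells) + np.sqrt(
            s2.var_total * s2.K_cells) + 1e-12
        assert np.median(num / scale) < 1.5

    def test_requires_two_trajectories(self, clock_dark):
        with pytest.raises(ValueError):
            model_spectrum(clock_dark, 1, 32, 16.0, seed=0)
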