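"""Multitaper estimation, spectrum decomposition and gamma screening stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaidgamma import (SpectrumGroundTruth, estimate_spectrum, fit_spectrum,
                        gamma_snr, gamma_zscore, generate_spectrum)
from plaidgamma.spectra import baseline_shape, gaussian_bump
from plaidgamma.synth import default_freq_grid


class TestModelShapes:
    @given(f0=st.floats(0.0, 20.0), n0=st.floats(0.2, 6.0),
           b0=st.floats(0.5, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_baseline_value_at_knee_and_monotone_decay(self, f0, n0, b0):
        assert baseline_shape(f0, f0, n0, b0) == pytest.approx(b0 ** -n0)
        f = np.linspace(f0 + 0.5, 200.0, 100)
        assert np.all(np.diff(baseline_shape(f, f0, n0, b0)) < 0)

    @given(u=st.floats(30.0, 100.0), sigma=st.floats(0.5, 20.0))
    @settings(max_examples=50, derandomize=True)
    def test_gaussian_bounded_and_peaks_at_u(self, u, sigma):
        f = np.linspace(0.0, 200.0, 401)
        g = gaussian_bump(f, u, sigma)
        assert np.all((g >= 0) & (g <= 1))  # far tails underflow to 0
        near = np.abs(f - u) < 8 * sigma
        assert np.all(g[near] > 0)
        assert gaussian_bump(u, u, sigma) == pytest.approx(1.0)


class TestEstimateSpectrum:
    def test_sinusoid_peak_localized(self):
        sf = 500.0
        t = np.arange(0, 2.2, 1 / sf)
        x = np.tile(np.sin(2 * np.pi * 60.0 * t), (3, 1))
        ss = estimate_spectrum(x, sf)
        df = ss.freqs[1] - ss.freqs[0]
        assert abs(ss.freqs[np.argmax(ss.mean())] - 60.0) <= df

    def test_white_noise_integrated_power_matches_variance(self, rng):
        sf = 500.0
        n = int(2.2 * sf)
        sigma = 2.0
        x = sigma * rng.standard_normal((150, n))
        ss = estimate_spectrum(x, sf)
        df = ss.freqs[1] - ss.freqs[0]
        assert ss.mean().sum() * df == pytest.approx(sigma**2, rel=0.10)

    def test_injected_narrowband_components_recovered(self, rng):
        sf = 500.0
        t = np.arange(0, 2.2, 1 / sf)
        ph = rng.uniform(0, 2 * np.pi, (20, 1))
        x = (rng.standard_normal((20, t.size))
             + 3.0 * np.sin(2 * np.pi * 50.0 * t + ph)
             + 2.5 * np.sin(2 * np.pi * 80.0 * t + 1.7 * ph))
        ss = estimate_spectrum(x, sf)
        m = ss.mean()
        for target in (50.0, 80.0):
            band = (ss.freqs > target - 10) & (ss.freqs < target + 10)
            assert abs(ss.freqs[band][np.argmax(m[band])] - target) < 2.0

    def test_window_outside_trace_raises(self):
        with pytest.raises(ValueError, match="window"):
            estimate_spectrum(np.zeros((2, 100)), 500.0, window=(0.3, 2.0))


class TestFitSpectrum:
    def test_noiseless_parameters_recovered_within_one_percent(
            self, spectrum_truth, freq_grid):
        fit = fit_spectrum(spectrum_truth.analytic(freq_grid), freq_grid,
                           n_restarts=10, seed=0)
        assert fit.converged
        for name, true in spectrum_truth.as_params().items():
            assert fit.params[name] == pytest.approx(true, rel=0.01), name
        assert fit.gof > 0.999

    def test_no_oscillation_spectrum_gets_negligible_bumps(self, freq_grid):
        gt = SpectrumGroundTruth(wg1=0.0, wg2=0.0)
        fit = fit_spectrum(gt.analytic(freq_grid), freq_grid, n_restarts=10, seed=0)
        # scale of the baseline inside the gamma bands
        scale = gt.wb * baseline_shape(np.array([gt.u1, gt.u2]), gt.f0, gt.n0, gt.b0)
        assert fit.params["wg1"] < 0.02 * scale[0]
        assert fit.params["wg2"] < 0.02 * scale[1]
        assert fit.gof > 0.99

    def test_scale_equivariance(self, spectrum_truth, freq_grid):
        # multiplying the spectrum by s rescales the weights and offset and
        # leaves every shape parameter unchanged
        power = spectrum_truth.analytic(freq_grid)
        f1 = fit_spectrum(power, freq_grid, n_restarts=5, seed=0)
        f2 = fit_spectrum(7.5 * power, freq_grid, n_restarts=5, seed=0)
        for name in ("wb", "wg1", "wg2", "k0"):
            assert f2.params[name] == pytest.approx(7.5 * f1.params[name], rel=1e-5)
        for name in ("f0", "n0", "b0", "u1", "sigma1", "u2", "sigma2"):
            assert f2.params[name] == pytest.approx(f1.params[name], rel=1e-5)

    def test_noisy_peak_recovery_majority(self, spectrum_truth, freq_grid):
        # a light version of the Monte-Carlo recovery study (the full one
        # runs in the acceptance suite)
        hits = 0
        for seed in range(20):
            spec = generate_spectrum(spectrum_truth, freq_grid, 10, seed=seed)
            fit = fit_spectrum(spec.mean(), freq_grid, n_restarts=4, seed=seed)
            hits += (abs(fit.params["u1"] - 50.0) <= 2.0
                     and abs(fit.params["u2"] - 80.0) <= 2.0)
        assert hits >= 18

    def test_band_validation(self, freq_grid, spectrum_truth):
        with pytest.raises(ValueError):
            fit_spectrum(spectrum_truth.analytic(freq_grid), freq_grid,
                         bands=((40.0, 80.0), (60.0, 100.0)))


class TestGammaScreening:
    def test_identical_spectra_not_significant(self, spectrum_truth, freq_grid):
        spec = generate_spectrum(spectrum_truth, freq_grid, 10, seed=0)
        stats = gamma_zscore(spec, spec)
        assert stats.zmax == pytest.approx(0.0)
        assert not stats.significant

    def test_constructed_exceedance_detected_in_band(self, spectrum_truth, freq_grid):
        blank = generate_spectrum(spectrum_truth, freq_grid, 10, seed=1)
        sd = blank.trials.std(axis=0, ddof=1)
        bump = np.where((freq_grid >= 55) & (freq_grid <= 65), 10.0 * sd, 0.0)
        stim = generate_spectrum(spectrum_truth, freq_grid, 10, seed=1)
        stim.trials = stim.trials + bump[None, :]
        stats = gamma_zscore(stim, blank)
        assert stats.significant
        assert 55.0 <= stats.zmax_freq <= 65.0

    def test_stimulus_gated_gamma_detected_across_seeds(self, freq_grid):
        # stimulus bumps five times the local baseline power vs a flat blank
        blank_gt = SpectrumGroundTruth(wg1=0.0, wg2=0.0)
        local = blank_gt.analytic(np.array([blank_gt.u1]))[0]
        stim_gt = SpectrumGroundTruth(wg1=5.0 * local, wg2=0.0)
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            stim = generate_spectrum(stim_gt, freq_grid, 10, seed=2 * seed)
            blank = generate_spectrum(blank_gt, freq_grid, 10, seed=2 * seed + 1)
            hits += gamma_zscore(stim, blank).significant
        assert hits >= 0.95 * n_seeds

    def test_gamma_snr_identity_and_ratio(self, spectrum_truth, freq_grid):
        fit = fit_spectrum(spectrum_truth.analytic(freq_grid), freq_grid,
                           n_restarts=5, seed=0)
        same = gamma_snr(fit, fit)
        assert same.lg == pytest.approx(1.0) and same.hg == pytest.approx(1.0)
        scaled_params = dict(fit.params)
        scaled_params["wg1"] = 3.0 * fit.params["wg1"]
        import dataclasses
        stim_fit = dataclasses.replace(fit, params=scaled_params)
        assert gamma_snr(stim_fit, fit).lg == pytest.approx(3.0)

    def test_blank_zero_weight_flagged_infinite(self, spectrum_truth, freq_grid):
        import dataclasses
        fit = fit_spectrum(spectrum_truth.analytic(freq_grid), freq_grid,
                           n_restarts=5, seed=0)
        blank_params = dict(fit.params)
        blank_params["wg1"] = 0.0
        blank = dataclasses.replace(fit, params=blank_params)
        res = gamma_snr(fit, blank)
        assert np.isinf(res.lg) and res.blank_wg_zero
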