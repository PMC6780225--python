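"""Demodulation, calibration and conversion arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fndtrace import (
    CalibrationCurve,
    ModulatedSpectrum,
    ModulationConfig,
    ParticleModel,
    demodulate,
    fit_calibration,
    mass_to_particles,
    per_cell_loading,
    quantify,
    recovery_rate,
    simulate_modulated_spectrum,
)
from fndtrace.synthetic import SpectrumModel

from conftest import lockin_amplitude

import pandas as pd


class TestDemodulate:
    @pytest.mark.parametrize("depth", [0.05, 0.1, 0.2])
    def test_square_wave_fundamental_is_2mI0_over_pi(self, depth):
        """A rate toggling between I0 and I0*(1-m) has fundamental 2*m*I0/pi."""
        model = SpectrumModel.default(
            brightness_per_conc=1000.0, background_level=0.0, drift_fraction=0.0
        )
        cfg = ModulationConfig(depth_m=depth)
        dem = demodulate(simulate_modulated_spectrum(model, cfg, 1.0, shot_noise=False))
        expected = 2.0 * depth * 1000.0 / math.pi
        assert dem.amplitude_at(685.0) == pytest.approx(expected, rel=1e-6)

    def test_constant_input_has_no_amplitude_at_f_mod(self):
        cfg = ModulationConfig()
        x = np.full((1, cfg.n_samples), 123.4)
        ms = ModulatedSpectrum(np.array([685.0]), cfg.times(), x, cfg)
        assert demodulate(ms).amplitudes[0] == pytest.approx(0.0, abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(arrays(float, 60, elements=st.floats(0.0, 1000.0)))
    def test_fft_bin_equals_bruteforce_lockin(self, x):
        """On small inputs the FFT-bin amplitude equals direct sin/cos
        integration to 1e-10 relative (odd samples-per-period, no square-wave
        rescaling involved)."""
        cfg = ModulationConfig(f_mod_hz=1.0, sample_rate_hz=15.0, duration_s=4.0)
        ms = ModulatedSpectrum(np.array([685.0]), cfg.times(), x[None, :], cfg)
        got = demodulate(ms, detrend=False).amplitudes[0]
        want = lockin_amplitude(x, 15.0, 1.0)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_even_period_convention_rescales_by_aliasing_factor(self):
        """With P = fs/f_mod even, reported amplitudes are the lock-in value
        times P*sin(pi/P)/pi (continuous-waveform scale)."""
        rng = np.random.default_rng(0)
        cfg = ModulationConfig(f_mod_hz=2.0, sample_rate_hz=20.0, duration_s=3.0)
        x = rng.uniform(0.0, 100.0, size=cfg.n_samples)
        ms = ModulatedSpectrum(np.array([685.0]), cfg.times(), x[None, :], cfg)
        got = demodulate(ms, detrend=False).amplitudes[0]
        p = 10.0
        want = lockin_amplitude(x, 20.0, 2.0) * p * np.sin(np.pi / p) / np.pi
        assert got == pytest.approx(want, rel=1e-10)

    def test_slow_offgrid_drift_changes_amplitude_below_one_percent(self):
        """Additive background varying slower than f_mod/10 perturbs the
        demodulated amplitude by < 1% of the true modulated amplitude."""
        cfg = ModulationConfig(depth_m=0.2)
        t = cfg.times()
        sig = 1000.0 * (1.0 - 0.2 * cfg.field_on(t))
        truth = 2.0 * 0.2 * 1000.0 / math.pi
        for f0 in (0.013, 0.05, 0.11, 0.19):
            bg = 1e4 * (1.0 + 0.05 * np.sin(2.0 * np.pi * f0 * t + 1.0))
            ms = ModulatedSpectrum(
                np.array([685.0]), t, ((sig + bg) / cfg.sample_rate_hz)[None, :], cfg
            )
            dev = abs(demodulate(ms).amplitudes[0] - truth) / truth
            assert dev < 0.01, f"drift at {f0} Hz deviated {100 * dev:.2f}%"

    def test_recovery_under_tenfold_autofluorescence(self):
        """Simulated tissue-digest spectrum: amplitude recovered within
        3 noise-floor units of ground truth."""
        conc = 50.0
        model = SpectrumModel.default(
            brightness_per_conc=500.0, background_level=10.0 * conc * 500.0
        )
        ms = simulate_modulated_spectrum(model, ModulationConfig(), conc, seed=42)
        dem = demodulate(ms)
        truth = ms.meta["true_amplitude"]
        idx = np.argmin(np.abs(dem.wavelengths_nm - 685.0))
        assert abs(dem.amplitudes[idx] - truth[idx]) < 3.0 * dem.noise_floor[idx]

    def test_offgrid_frequency_without_fallback_raises(self):
        cfg = ModulationConfig(f_mod_hz=2.0, sample_rate_hz=20.0, duration_s=3.0)
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, size=(1, 55))  # truncated record: f_mod off-grid
        ms = ModulatedSpectrum(np.array([685.0]), np.arange(55) / 20.0, x, cfg)
        with pytest.raises(ValueError, match="grid"):
            demodulate(ms, window_fallback=False, detrend=False)
        dem = demodulate(ms, window_fallback=True, detrend=False)
        assert dem.windowed


class TestCalibration:
    def test_noiseless_proportional_table_recovers_slope_and_zero_lod(self):
        conc = np.array([0.0, 0.0, 5.0, 10.0, 50.0, 100.0])
        table = pd.DataFrame(
            {"concentration_ug_per_ml": conc, "amplitude": 2.5 * conc, "replicate": 0}
        )
        cal = fit_calibration(table)
        assert cal.slope == pytest.approx(2.5)
        assert cal.lod == pytest.approx(0.0)
        assert cal.intercept == 0.0

    def test_blanks_only_table_fails(self):
        table = pd.DataFrame(
            {"concentration_ug_per_ml": [0.0] * 5, "amplitude": [1.0] * 5, "replicate": 0}
        )
        with pytest.raises(ValueError, match="3 distinct non-zero"):
            fit_calibration(table)

    def test_quantify_divides_amplitude_by_slope(self):
        cal = CalibrationCurve(slope=2.546, residual_sd=0.0, blank_sd=0.0, lod=0.0)
        from fndtrace import DemodulatedSpectrum

        dem = DemodulatedSpectrum(
            wavelengths_nm=np.array([680.0, 685.0, 690.0]),
            amplitudes=np.array([0.0, 254.6, 0.0]),
            noise_floor=np.zeros(3),
            f_mod_hz=2.0,
        )
        q = quantify(dem, cal, 685.0)
        assert q.concentration_ug_per_ml == pytest.approx(100.0)
        assert not q.below_detection

    def test_zero_amplitude_is_flagged_below_detection(self):
        from fndtrace import DemodulatedSpectrum

        cal = CalibrationCurve(slope=2.0, residual_sd=0.1, blank_sd=0.5, lod=0.825)
        dem = DemodulatedSpectrum(
            wavelengths_nm=np.array([685.0]),
            amplitudes=np.array([0.0]),
            noise_floor=np.array([0.5]),
            f_mod_hz=2.0,
        )
        q = quantify(dem, cal, 685.0)
        assert q.concentration_ug_per_ml == 0.0
        assert q.below_detection


class TestConversions:
    def test_49_3_pg_of_100nm_diamond_is_2_7e4_particles(self):
        res = mass_to_particles(49.3, ParticleModel(100.0, 3.52))
        assert res.count_2sf == pytest.approx(2.7e4)

    def test_zero_mass_zero_particles(self):
        assert mass_to_particles(0.0).count == 0.0

    def test_count_scales_inverse_cubed_with_diameter(self):
        small = mass_to_particles(10.0, ParticleModel(100.0, 3.52)).count
        big = mass_to_particles(10.0, ParticleModel(200.0, 3.52)).count
        assert small / big == pytest.approx(8.0)

    def test_nonpositive_particle_dimensions_fail(self):
        with pytest.raises(ValueError):
            ParticleModel(diameter_nm=0.0)

    def test_per_cell_loading_ratio(self):
        res = per_cell_loading(4.93e6, 1e5)
        assert res.mean_pg_per_cell == pytest.approx(49.3)
        assert per_cell_loading(4.93e6, 2e5).mean_pg_per_cell == pytest.approx(49.3 / 2)

    def test_per_cell_loading_replicates_report_sem(self):
        res = per_cell_loading([48.0e5, 50.0e5, 50.0e5], 1e5)
        assert res.mean_pg_per_cell == pytest.approx(49.333333, rel=1e-6)
        assert res.sem_pg_per_cell == pytest.approx(np.std([48, 50, 50], ddof=1) / np.sqrt(3))

    def test_per_cell_loading_zero_cells_fails(self):
        with pytest.raises(ValueError):
            per_cell_loading(1.0, 0)

    def test_recovery_rate_identity_and_scaling(self):
        assert recovery_rate([1.0, 2.0], [1.0, 2.0]) == pytest.approx(100.0)
        assert recovery_rate([1.0, 2.0], [0.9, 1.8]) == pytest.approx(90.0)
        with pytest.raises(ValueError):
            recovery_rate([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            recovery_rate([1.0], [1.0, 2.0])


class TestEndToEndLinearity:
    def test_noiseless_amplitude_proportional_to_concentration(self):
        """Forward model linearity: doubling concentration exactly doubles
        the demodulated amplitude at every wavelength."""
        model = SpectrumModel.default(
            brightness_per_conc=400.0, background_level=2e3, drift_fraction=0.0
        )
        cfg = ModulationConfig()
        a1 = demodulate(simulate_modulated_spectrum(model, cfg, 30.0, shot_noise=False)).amplitudes
        a2 = demodulate(simulate_modulated_spectrum(model, cfg, 60.0, shot_noise=False)).amplitudes
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-10)

    def test_closed_loop_concentration_recovery_within_5_percent(self):
        """simulate -> demodulate -> quantify at 100 ug/mL, default noise:
        mean absolute relative error below 5% over seeded replicates."""
        slope = 2.0 * 0.1 * 500.0 / math.pi
        cal = CalibrationCurve(slope=slope, residual_sd=0.0, blank_sd=0.0, lod=0.0)
        model = SpectrumModel.default(brightness_per_conc=500.0, background_level=1e4)
        errs = []
        for seed in range(30):
            ms = simulate_modulated_spectrum(model, ModulationConfig(), 100.0, seed=seed)
            q = quantify(demodulate(ms), cal, 685.0)
            errs.append(abs(q.concentration_ug_per_ml - 100.0) / 100.0)
        assert np.mean(errs) < 0.05
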