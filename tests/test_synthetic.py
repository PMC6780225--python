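"""Forward simulators: invariant enforcement, noise realism, ground truth."""

import numpy as np
import pytest

from fndtrace import (
    DecayModel,
    FieldSpec,
    ModulationConfig,
    demodulate,
    fit_calibration,
    simulate_calibration_series,
    simulate_decay_histogram,
    simulate_field,
    simulate_modulated_spectrum,
)
from fndtrace.synthetic import SpectrumModel


class TestModulationConfig:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"f_mod_hz": 0.0}, "f_mod"),
            ({"sample_rate_hz": 5.0}, "sample_rate"),
            ({"duration_s": 60.3}, "integer number"),
            ({"depth_m": 1.0}, "depth_m"),
            ({"depth_m": -0.1}, "depth_m"),
        ],
    )
    def test_invalid_configs_name_the_violated_invariant(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            ModulationConfig(**kwargs)

    def test_square_wave_is_half_duty_field_off_first(self):
        cfg = ModulationConfig()
        on = cfg.field_on(cfg.times())
        assert not on[0]  # off-first
        assert on.mean() == pytest.approx(0.5)


class TestModulatedSpectrum:
    def test_negative_concentration_rejected(self, clean_model, default_config):
        with pytest.raises(ValueError, match="fnd_conc"):
            simulate_modulated_spectrum(clean_model, default_config, -1.0)

    def test_zero_depth_leaves_no_signal_at_f_mod(self):
        """With no magnetic quench there is no modulation: the amplitude at
        f_mod stays at the Poisson noise floor."""
        model = SpectrumModel.default(brightness_per_conc=500.0, background_level=1e4)
        cfg = ModulationConfig(depth_m=0.0)
        dem = demodulate(simulate_modulated_spectrum(model, cfg, 100.0, seed=5))
        idx = np.argmin(np.abs(dem.wavelengths_nm - 685.0))
        assert dem.amplitudes[idx] < 5.0 * dem.noise_floor[idx]

    def test_ground_truth_amplitude_attached(self, clean_model, default_config):
        ms = simulate_modulated_spectrum(clean_model, default_config, 2.0, shot_noise=False)
        idx = np.argmin(np.abs(ms.wavelengths_nm - 685.0))
        assert ms.meta["true_amplitude"][idx] == pytest.approx(
            2.0 * default_config.depth_m * 2.0 * 1000.0 / np.pi
        )

    def test_poisson_noise_variance_matches_mean(self):
        """Shot-noise realism: sample variance/mean -> 1 (within 5% at 1e5
        samples) for an unmodulated, drift-free rate."""
        model = SpectrumModel.default(
            wl_step_nm=125.0, brightness_per_conc=0.0, background_level=2e3, drift_fraction=0.0
        )
        cfg = ModulationConfig(depth_m=0.0, duration_s=5000.0)
        ms = simulate_modulated_spectrum(model, cfg, 0.0, seed=3)
        row = ms.intensities[np.argmin(np.abs(ms.wavelengths_nm - 675.0))]
        assert row.size == 100_000
        assert row.var() / row.mean() == pytest.approx(1.0, abs=0.05)

    def test_seeded_reproducibility(self, clean_model, default_config):
        a = simulate_modulated_spectrum(clean_model, default_config, 5.0, seed=9)
        b = simulate_modulated_spectrum(clean_model, default_config, 5.0, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestDecaySimulator:
    def test_pure_fnd_mean_arrival_time_equals_tau(self):
        """Mean of an exponential is tau; use a window long enough that
        truncation is negligible."""
        model = DecayModel(
            fraction_fnd=1.0, irf_sigma_ns=0.0, bin_width_ns=0.25, n_bins=1200, total_photons=100_000
        )
        h = simulate_decay_histogram(model, seed=1)
        mean = np.sum(h.bin_centers_ns * h.counts) / h.total
        assert mean == pytest.approx(17.0, abs=3 * 17.0 / np.sqrt(1e5) + 0.15)

    def test_autofluorescence_tail_probability(self):
        """P(arrival > 10 ns) for tau = 2 ns is exp(-5) ~ 0.0067."""
        model = DecayModel(
            tau_fnd_ns=17.0, tau_auto_ns=2.0, fraction_fnd=0.0, irf_sigma_ns=0.0,
            bin_width_ns=0.2, n_bins=600, total_photons=100_000,
        )
        h = simulate_decay_histogram(model, seed=2)
        p = np.exp(-5.0)
        frac = h.counts[h.bin_centers_ns > 10.0].sum() / h.total
        se = np.sqrt(p * (1 - p) / 1e5)
        assert abs(frac - p) < 3.0 * se + 1e-4

    def test_zero_photons_gives_empty_histogram(self):
        h = simulate_decay_histogram(DecayModel(total_photons=0), seed=0)
        assert h.total == 0

    def test_component_labels_are_retained(self):
        h = simulate_decay_histogram(DecayModel(), seed=4)
        comp = h.meta["component_counts"]
        assert set(comp) == {"fnd", "auto"}

    def test_lifetime_ordering_enforced(self):
        with pytest.raises(ValueError, match="tau_fnd > tau_auto"):
            DecayModel(tau_fnd_ns=2.0, tau_auto_ns=17.0)

    def test_short_window_warns_about_truncation(self):
        with pytest.warns(UserWarning, match="truncation"):
            simulate_decay_histogram(DecayModel(n_bins=100, bin_width_ns=0.2), seed=0)


class TestFieldSimulator:
    def test_fixed_seed_is_byte_identical(self):
        a = simulate_field(FieldSpec(seed=11))
        b = simulate_field(FieldSpec(seed=11))
        for name in a.channels:
            assert a.channels[name].tobytes() == b.channels[name].tobytes()

    def test_ground_truth_recorded(self):
        f = simulate_field(FieldSpec(n_nuclei=10, fnd_labeled_fraction=0.5, seed=1))
        assert f.provenance["centers_px"].shape == (10, 2)
        assert f.provenance["fnd_labeled"].sum() == 5

    def test_overcrowded_field_fails_with_density_message(self):
        with pytest.raises(RuntimeError, match="non-overlapping"):
            simulate_field(FieldSpec(image_shape=(64, 64), n_nuclei=200, seed=0))

    def test_nuclei_respect_hard_core_separation(self):
        f = simulate_field(FieldSpec(seed=3))
        c = f.provenance["centers_px"]
        d = np.sqrt(((c[None, :, :] - c[:, None, :]) ** 2).sum(-1))
        d[np.diag_indices_from(d)] = np.inf
        r_px = 5.0 / 0.65
        assert d.min() >= 3.0 * r_px - 1e-9


class TestCalibrationSeries:
    def test_requires_a_blank(self, clean_model, default_config):
        with pytest.raises(ValueError, match="blank"):
            simulate_calibration_series(clean_model, default_config, (5.0, 10.0, 50.0))

    def test_noiseless_series_is_exactly_proportional(self):
        model = SpectrumModel.default(
            brightness_per_conc=500.0, background_level=1e3, drift_fraction=0.0
        )
        table = simulate_calibration_series(
            model, ModulationConfig(), (0.0, 5.0, 10.0, 50.0), shot_noise=False
        )
        conc = table["concentration_ug_per_ml"].to_numpy()
        amp = table["amplitude"].to_numpy()
        slope = 2.0 * 0.1 * 500.0 / np.pi
        np.testing.assert_allclose(amp, slope * conc, rtol=1e-9, atol=1e-9)

    def test_labeling_range_series_is_monotone(self):
        """Mean amplitudes increase over the 5-200 ug/mL labeling range."""
        model = SpectrumModel.default(brightness_per_conc=500.0, background_level=1e4)
        table = simulate_calibration_series(
            model, ModulationConfig(), (0, 5, 10, 50, 100, 200), replicates=2, seed=8
        )
        means = table.groupby("concentration_ug_per_ml")["amplitude"].mean()
        assert (np.diff(means.to_numpy()) > 0).all()

    def test_all_blank_series_cannot_be_fit(self, default_config):
        model = SpectrumModel.default(brightness_per_conc=500.0, background_level=1e4)
        table = simulate_calibration_series(model, default_config, (0.0, 0.0, 0.0), seed=1)
        with pytest.raises(ValueError):
            fit_calibration(table)
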