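"""Tests of the synthetic LC / spectra / cube generators."""

import numpy as np
import pytest
from scipy import stats

import spectrafuse as sf
from spectrafuse.radiometry import (DegenerateDenominatorError,
                                    mean_cube_spectrum, relative_reflectance)
from spectrafuse.synthetic import (Band, CubeSpec, LCDistribution, SensorSpec,
                                   generate_cube, generate_sensor_spectra,
                                   generate_two_sensor, sample_lc)
from conftest import FL1879, NORKOTAH, small_config


class TestSampleLC:
    def test_range_and_skew_at_study_size(self):
        for seed in range(1, 11):
            lc = sample_lc(200, FL1879, seed)
            assert lc.min() >= FL1879.target_min
            assert lc.max() <= FL1879.target_max
            assert stats.skew(lc) > 0

    def test_moment_targets_over_repeated_seeds(self):
        means = [sample_lc(200, FL1879, s).mean() for s in range(1, 11)]
        sds = [sample_lc(200, FL1879, s).std(ddof=1) for s in range(1, 11)]
        assert abs(np.mean(means) - 13.47) <= 0.15 * 13.47
        assert abs(np.mean(sds) - 13.62) <= 0.25 * 13.62

    def test_degenerate_distribution_is_constant(self):
        lc = sample_lc(5, LCDistribution(10.0, 10.0, 10.0, 0.0), 0)
        assert np.all(lc == 10.0)

    def test_large_sample_mean_calibration(self):
        # Monte-Carlo check of the generator's own clipped-moment calibration
        lc = sample_lc(10_000, NORKOTAH, 3)
        assert abs(lc.mean() - 12.96) <= 0.5

    @pytest.mark.parametrize("n, dist", [
        (0, FL1879),
        (-3, FL1879),
        (10, LCDistribution(20.0, 10.0, 15.0, 2.0)),   # min > max
        (10, LCDistribution(4.0, 50.0, 13.0, -1.0)),   # negative SD
    ])
    def test_invalid_inputs(self, n, dist):
        with pytest.raises(ValueError):
            sample_lc(n, dist, 0)


class TestSensorSpectra:
    def test_same_seed_bit_identical(self):
        cfg = small_config(seed=5)
        (a1, b1), t1 = generate_two_sensor(cfg)
        (a2, b2), t2 = generate_two_sensor(cfg)
        assert np.array_equal(a1.X, a2.X)
        assert np.array_equal(b1.X, b2.X)
        assert np.array_equal(t1.lc, t2.lc)

    def test_no_signal_when_effect_zero(self):
        # with all effects zero, no column should correlate with LC beyond
        # the null sampling bound (Bonferroni-style 4/sqrt(n) across columns)
        spec = SensorSpec(
            name="s", n_wavelengths=120, wavelength_range=(400.0, 1000.0),
            informative_bands=[Band(600.0, 20.0, 0.0)],
            gain_sd=0.0, offset_sd=0.0, noise_sd=0.01)
        mean_abs_r, frac_above = [], []
        for seed in range(3):
            lc = sample_lc(200, FL1879, seed)
            ds, _ = generate_sensor_spectra(lc, spec, rng_seed=seed)
            r = np.array([np.corrcoef(lc, ds.X[:, j])[0, 1]
                          for j in range(ds.n_wavelengths)])
            mean_abs_r.append(np.mean(np.abs(r)))
            frac_above.append(np.mean(np.abs(r) > 0.1))
        # null |r| has SD 1/sqrt(200)=0.071: mean |r| must sit near the null
        # expectation and columns beyond 0.1 must stay a small minority
        assert np.mean(mean_abs_r) < 0.08
        assert np.mean(frac_above) < 0.35

    def test_noiseless_band_is_monotone_in_lc(self):
        spec = SensorSpec(
            name="s", n_wavelengths=100, wavelength_range=(400.0, 1000.0),
            informative_bands=[Band(700.0, 15.0, 0.02)],
            gain_sd=0.0, offset_sd=0.0, noise_sd=0.0)
        lc = sample_lc(50, FL1879, 7)
        ds, truth = generate_sensor_spectra(lc, spec, rng_seed=7)
        center = int(np.argmin(np.abs(ds.wavelengths - 700.0)))
        order = np.argsort(lc)
        col = ds.X[order, center]
        assert np.all(np.diff(col) >= 0)
        rho = stats.spearmanr(lc, ds.X[:, center]).statistic
        assert rho == pytest.approx(1.0)
        assert center in truth.band_indices["s"][0]

    def test_planted_signal_monotone_in_effect_size(self):
        lc = sample_lc(200, FL1879, 11)
        corrs = []
        for effect in (0.005, 0.01, 0.02, 0.04):
            spec = SensorSpec(
                name="s", n_wavelengths=100, wavelength_range=(400.0, 1000.0),
                informative_bands=[Band(700.0, 15.0, effect)],
                gain_sd=0.0, offset_sd=0.0, noise_sd=0.01)
            ds, _ = generate_sensor_spectra(lc, spec, rng_seed=11)
            center = int(np.argmin(np.abs(ds.wavelengths - 700.0)))
            corrs.append(abs(np.corrcoef(lc, ds.X[:, center])[0, 1]))
        assert np.all(np.diff(corrs) > 0)

    def test_default_single_sensor_plsr_quality(self):
        # frozen default generator: sensor 1 alone, full spectrum, 4 LVs
        from spectrafuse.evaluation import evaluate
        from spectrafuse.pipeline import split_dataset
        from spectrafuse.plsr import fit_pls, predict
        for seed in (1, 2, 3):
            cfg = sf.SyntheticConfig(seed=seed)
            (a, _), truth = generate_two_sensor(cfg)
            cal, pred = split_dataset(cfg.n_samples, 0.8, seed)
            y = np.sqrt(truth.lc)
            model = fit_pls(a.X[cal], y[cal], 4)
            rep = evaluate(y[pred], predict(model, a.X[pred]))
            assert rep.r > 0.7

    def test_invalid_inputs(self):
        spec = small_config().sensors[0]
        with pytest.raises(ValueError):
            generate_sensor_spectra(np.array([]), spec, 0)
        with pytest.raises(ValueError):
            generate_sensor_spectra(np.array([-1.0, 5.0]), spec, 0)
        with pytest.raises(ValueError, match="outside range"):
            SensorSpec(name="s", n_wavelengths=10,
                       wavelength_range=(400.0, 500.0),
                       informative_bands=[Band(900.0, 10.0, 0.01)])


class TestConfig:
    def test_identical_sensor_bands_rejected(self):
        s = small_config().sensors[0]
        import dataclasses
        twin = dataclasses.replace(s, name="other")
        with pytest.raises(ValueError, match="not be identical"):
            sf.SyntheticConfig(n_samples=20, sensors=[s, twin])

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            sf.SyntheticConfig(n_samples=5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(seed=3)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = sf.SyntheticConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestCube:
    def test_zero_noise_mean_recovers_exactly(self):
        spec = np.linspace(0.2, 0.8, 32)
        cube = generate_cube(spec, CubeSpec(5, 7, spatial_noise_sd=0.0), 0)
        as_s, as_b, as_r = mean_cube_spectrum(cube)
        rr = relative_reflectance(as_s, as_b, as_r)
        # exact up to the rounding of the spatial sum itself
        np.testing.assert_allclose(rr, spec, rtol=1e-14, atol=0)

    def test_noisy_mean_within_standard_error(self):
        spec = np.linspace(0.2, 0.8, 64)
        noise = 0.01
        cube = generate_cube(spec, CubeSpec(10, 50, spatial_noise_sd=noise), 1)
        as_s, as_b, as_r = mean_cube_spectrum(cube)
        rr = relative_reflectance(as_s, as_b, as_r)
        bound = 3 * noise / np.sqrt(10 * 50)
        assert np.all(np.abs(rr - spec) <= bound)

    def test_background_equal_reference_raises_downstream(self):
        spec = np.linspace(0.2, 0.8, 16)
        cube = generate_cube(
            spec, CubeSpec(3, 4, spatial_noise_sd=0.0,
                           background_level=0.5, reference_level=0.5), 0)
        with pytest.raises(DegenerateDenominatorError):
            relative_reflectance(*mean_cube_spectrum(cube))

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            generate_cube(np.ones(8), CubeSpec(0, 10), 0)
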