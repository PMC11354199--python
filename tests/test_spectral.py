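import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliafreq import (
    FrameStack,
    cbf_histogram,
    dominant_frequency_map,
    mean_psd_cbf,
    pixel_power_spectra,
)
from ciliafreq.synthetic import Region, SimConfig, simulate_cilia_stack

from conftest import make_sine_stack


def single_pixel_stack(x, fps=500.0):
    return FrameStack(np.asarray(x, dtype=float)[:, None, None], fps=fps)


class TestPixelPowerSpectra:
    def test_constant_stack_has_zero_power_off_dc(self):
        spec = pixel_power_spectra(FrameStack(np.full((64, 4, 4), 9.0), fps=500.0))
        np.testing.assert_array_equal(spec.psd[1:], 0.0)

    def test_on_grid_sinusoid_concentrates_in_one_bin(self):
        t = np.arange(1000) / 500.0
        spec = pixel_power_spectra(single_pixel_stack(20 * np.sin(2 * np.pi * 10.0 * t)))
        power = spec.psd[:, 0, 0]
        peak = np.nonzero(power > 1e-6 * power.max())[0]
        assert peak.size == 1
        assert spec.freqs[peak[0]] == 10.0

    def test_off_grid_peak_lands_in_adjacent_bin_and_band_power_matches_oracle(self):
        # 10.2 Hz sits between the 10.0 and 10.5 Hz grid lines at df = 0.5 Hz
        t = np.arange(1000) / 500.0
        x = 20 * np.sin(2 * np.pi * 10.2 * t)
        spec = pixel_power_spectra(single_pixel_stack(x))
        power = spec.psd[:, 0, 0]
        idx = spec.band_indices
        peak_freq = spec.freqs[idx[np.argmax(power[idx])]]
        assert peak_freq in (10.0, 10.5)
        # oracle: a dense zero-padded DFT locates the true peak at 10.2 Hz,
        # within half a coarse bin of the gridded estimate
        xc = x - x.mean()
        n_dense = 2**16
        dense = np.abs(np.fft.rfft(xc, n=n_dense)) ** 2
        dense_freqs = np.fft.rfftfreq(n_dense, d=1 / 500.0)
        dense_peak = dense_freqs[np.argmax(dense)]
        assert abs(dense_peak - 10.2) < 0.01
        assert abs(peak_freq - dense_peak) <= spec.df / 2 + 1e-9
        # and the one-sided power total matches the time-domain energy (closed form)
        assert abs(power.sum() - (xc**2).sum()) / (xc**2).sum() < 1e-10
        assert power[idx].sum() / power.sum() > 0.99  # leakage mostly stays in band

    def test_parseval_identity_per_pixel(self, rng):
        frames = rng.normal(100, 15, size=(128, 5, 6))
        stack = FrameStack(frames, fps=500.0)
        spec = pixel_power_spectra(stack)
        np.testing.assert_allclose(
            spec.psd.sum(axis=0), 128 * frames.var(axis=0), rtol=1e-10
        )

    @given(n_frames=st.sampled_from([500, 1000]))
    @settings(max_examples=2, deadline=None, derandomize=True)
    def test_grid_spacing_is_fps_over_n(self, n_frames):
        stack, _ = make_sine_stack(n_frames=1000)
        spec = pixel_power_spectra(stack, n_frames=n_frames)
        assert spec.df == 500.0 / n_frames  # 0.5 Hz at 1000 frames, 1.0 Hz at 500

    def test_requesting_more_frames_than_available_is_rejected(self, sine_stack):
        with pytest.raises(ValueError, match="frames"):
            pixel_power_spectra(sine_stack[0], n_frames=5000)

    def test_band_outside_nyquist_is_rejected(self, sine_stack):
        with pytest.raises(ValueError, match="band"):
            pixel_power_spectra(sine_stack[0], band=(1.0, 400.0))


class TestMeanPsdCbf:
    def test_uniform_frequency_recovers_exactly(self, sine_stack):
        spec = pixel_power_spectra(sine_stack[0])
        assert mean_psd_cbf(spec).value_hz == 10.0

    def test_peak_follows_amplitude_squared_weighting(self):
        # equal-area regions: 8 Hz at amplitude 20 dominates 12 Hz at amplitude 10
        cfg = SimConfig(
            fps=500.0, n_frames=1000, height=32, width=32,
            regions=[
                Region(("rect", 0, 0, 16, 32), cbf_hz=8.0, amplitude=20.0),
                Region(("rect", 16, 0, 16, 32), cbf_hz=12.0, amplitude=10.0),
            ],
            quantize_output=False,
        )
        stack, _ = simulate_cilia_stack(cfg)
        spec = pixel_power_spectra(stack)
        est = mean_psd_cbf(spec)
        assert est.value_hz == 8.0
        # brute-force check: the averaged spectrum really is larger at 8 than 12 Hz
        mean_psd = spec.psd.reshape(spec.psd.shape[0], -1).mean(axis=1)
        i8 = int(np.argmin(np.abs(spec.freqs - 8.0)))
        i12 = int(np.argmin(np.abs(spec.freqs - 12.0)))
        assert mean_psd[i8] > mean_psd[i12]

    def test_constant_stack_has_no_power_in_band(self):
        spec = pixel_power_spectra(FrameStack(np.full((64, 4, 4), 9.0), fps=500.0))
        with pytest.raises(ValueError, match="no spectral power"):
            mean_psd_cbf(spec)

    def test_noise_robustness_at_snr_ten(self):
        # SNR = A^2 / (2 sigma^2) = 10: on-grid recovery in >= 99 of 100 replicates
        hits = 0
        for seed in range(100):
            stack, _ = make_sine_stack(
                cbf_hz=10.0, n_frames=500, shape=(8, 8), mask=("rect", 0, 0, 8, 8),
                amplitude=20.0, noise_sigma=np.sqrt(400.0 / 20.0), seed=seed,
            )
            spec = pixel_power_spectra(stack)
            hits += mean_psd_cbf(spec).value_hz == 10.0
        assert hits >= 99


class TestDominantFrequencyMap:
    def test_uniform_region_maps_to_constant(self, sine_stack):
        stack, truth = sine_stack
        fmap = dominant_frequency_map(pixel_power_spectra(stack), variance_floor=1e-9)
        mask = np.isfinite(truth.frequency_map)
        np.testing.assert_array_equal(fmap[mask], 10.0)
        assert np.all(np.isnan(fmap[~mask]))

    def test_two_region_map_matches_ground_truth_exactly(self):
        cfg = SimConfig(
            fps=500.0, n_frames=1000, height=20, width=20,
            regions=[
                Region(("rect", 0, 0, 12, 20), cbf_hz=8.0),
                Region(("rect", 12, 0, 8, 20), cbf_hz=12.0),
            ],
            quantize_output=False,
        )
        stack, truth = simulate_cilia_stack(cfg)
        fmap = dominant_frequency_map(pixel_power_spectra(stack), variance_floor=1e-9)
        np.testing.assert_array_equal(fmap, truth.frequency_map)

    def test_default_variance_floor_analyzes_every_pixel_with_noise(self):
        stack, _ = make_sine_stack(noise_sigma=2.0, seed=5)
        fmap = dominant_frequency_map(pixel_power_spectra(stack))
        assert np.isfinite(fmap).all()


class TestCbfHistogram:
    def test_uniform_map_gives_single_full_bin(self):
        dist, est = cbf_histogram(np.full((10, 10), 10.0), bin_width=0.5)
        assert est.value_hz == 10.0
        occupied = dist.counts > 0
        assert occupied.sum() == 1
        assert dist.percentages[occupied][0] == 100.0

    def test_area_split_yields_matching_percentages_and_low_mode(self):
        fmap = np.full((10, 10), 12.0)
        fmap[:6] = 8.0  # 60 % of pixels at 8 Hz, 40 % at 12 Hz
        dist, est = cbf_histogram(fmap, bin_width=0.5)
        assert est.value_hz == 8.0
        centers = dist.bin_centers
        assert dist.percentages[np.argmin(np.abs(centers - 8.0))] == 60.0
        assert dist.percentages[np.argmin(np.abs(centers - 12.0))] == 40.0

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_percentages_always_sum_to_100_and_counts_to_defined_pixels(self, seed):
        rng = np.random.default_rng(seed)
        fmap = rng.uniform(1.0, 30.0, size=(12, 12))
        fmap[rng.random((12, 12)) < 0.3] = np.nan
        if not np.isfinite(fmap).any():
            return
        dist, _ = cbf_histogram(fmap, bin_width=0.5)
        np.testing.assert_allclose(dist.percentages.sum(), 100.0)
        assert dist.counts.sum() == np.isfinite(fmap).sum()

    def test_fully_undefined_map_is_rejected(self):
        with pytest.raises(ValueError, match="no defined pixels"):
            cbf_histogram(np.full((4, 4), np.nan))


def test_estimators_agree_on_single_frequency_synthetics(sine_stack):
    stack, _ = sine_stack
    spec = pixel_power_spectra(stack)
    peak = mean_psd_cbf(spec).value_hz
    fmap = dominant_frequency_map(spec, variance_floor=1e-9)
    _, mode = cbf_histogram(fmap, bin_width=spec.df)
    assert peak == mode.value_hz == 10.0
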