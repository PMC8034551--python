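"""Reference SLSC computation, GPU-style approximation, DAS and resampling."""

import numpy as np
import pytest
from helpers import coherence_oracle, slsc_image_oracle
from hypothesis import given
from hypothesis import strategies as st

from coherenet import (
    CoherenceFunction,
    FrameMeta,
    KernelBlock,
    SLSCParams,
    ChannelData,
    coherence_batch,
    coherence_cpu,
    das_image,
    resample_channel_data,
    slsc_image_cpu,
    slsc_image_gpu_style,
    slsc_value,
    zero_mean_kernel,
)


def _random_block(rng, k=7, n=8):
    return rng.standard_normal((k, n))


class TestZeroMean:
    def test_constant_channel_becomes_zero(self):
        block = KernelBlock(np.ones((7, 4)))
        out = zero_mean_kernel(block)
        assert out.zero_meaned
        np.testing.assert_array_equal(out.samples, np.zeros((7, 4)))

    def test_idempotent_on_zero_mean_input(self, rng):
        z = rng.standard_normal((7, 4))
        z -= z.mean(axis=0)
        out = zero_mean_kernel(KernelBlock(z))
        np.testing.assert_allclose(out.samples, z, atol=1e-15)

    def test_ramp_column(self):
        col = np.arange(1.0, 8.0)
        block = KernelBlock(np.stack([col, col], axis=1))
        out = zero_mean_kernel(block)
        np.testing.assert_array_equal(out.samples[:, 0], col - 4.0)


class TestCoherence:
    def test_identical_channels_fully_coherent(self, rng):
        g = rng.standard_normal(7)
        coh = coherence_cpu(np.tile(g[:, None], (1, 8)))
        np.testing.assert_allclose(coh.values[:7], 1.0, atol=1e-12)
        assert coh.values[7] == 0.0  # lag N is an empty sum

    def test_alternating_sign_channels(self, rng):
        g = rng.standard_normal(7)
        block = np.tile(g[:, None], (1, 8)) * (-1.0) ** np.arange(8)
        coh = coherence_cpu(block).values
        assert coh[0] == pytest.approx(-1.0, abs=1e-12)
        assert coh[1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        block = _random_block(rng)
        np.testing.assert_allclose(
            coherence_cpu(block).values, coherence_oracle(block), atol=1e-12
        )

    def test_zero_energy_channel_contributes_zero(self, rng):
        block = _random_block(rng)
        block[:, 3] = 5.0  # constant -> zero energy after zero-meaning
        values = coherence_cpu(block).values
        np.testing.assert_allclose(values, coherence_oracle(block), atol=1e-12)
        assert np.all(np.abs(values) <= 1.0 + 1e-12)

    def test_all_degenerate_lag_yields_zero(self):
        coh = coherence_cpu(np.ones((7, 4)))
        np.testing.assert_array_equal(coh.values, np.zeros(4))

    def test_rejects_bad_shapes(self, rng):
        with pytest.raises(ValueError):
            coherence_batch(rng.standard_normal((2, 0, 8)))
        with pytest.raises(ValueError):
            coherence_batch(rng.standard_normal((2, 7, 1)))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3), sign=st.sampled_from([-1.0, 1.0]))
    def test_scale_invariance(self, scale, sign):
        block = np.random.default_rng(42).standard_normal((7, 8))
        base = coherence_cpu(block).values
        scaled = coherence_cpu(block * (sign * scale)).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_values_bounded_by_cauchy_schwarz(self, seed):
        block = np.random.default_rng(seed).standard_normal((5, 6))
        values = coherence_cpu(block).values
        assert np.all(np.abs(values) <= 1.0 + 1e-12)

    def test_exact_channel_reversal_invariance(self, rng):
        # Reversing channel order maps each lag-m pair onto another lag-m
        # pair, so the average is exactly unchanged.
        block = _random_block(rng)
        fwd = coherence_cpu(block).values
        rev = coherence_cpu(block[:, ::-1]).values
        np.testing.assert_allclose(fwd, rev, atol=1e-12)


class TestSlscValue:
    def test_closed_forms(self):
        ones = CoherenceFunction(values=np.ones(64), n_lags=64)
        assert slsc_value(ones, 25) == 25.0
        zeros = CoherenceFunction(values=np.zeros(64), n_lags=64)
        assert slsc_value(zeros, 25) == 0.0
        tri = CoherenceFunction(values=1 - np.arange(1, 65) / 64.0, n_lags=64)
        assert slsc_value(tri, 25) == pytest.approx(19.921875, abs=1e-12)

    def test_out_of_range_lag(self):
        coh = CoherenceFunction(values=np.zeros(8), n_lags=8)
        with pytest.raises(ValueError):
            slsc_value(coh, 9)
        with pytest.raises(ValueError):
            slsc_value(coh, 0)


class TestSlscImageCpu:
    def test_matches_scalar_oracle(self, rng):
        samples = rng.standard_normal((20, 8, 2))
        data = ChannelData(
            samples=samples,
            meta=FrameMeta(n_channels=8, center_freq_hz=5e6, sampling_freq_hz=20e6),
        )
        params = SLSCParams(kernel_len=7, short_lag=5)
        img = slsc_image_cpu(data, params)
        oracle = slsc_image_oracle(samples, 7, 5)
        assert img.pixels.shape == oracle.shape == (14, 2)
        np.testing.assert_allclose(img.pixels, oracle, atol=1e-12)

    def test_identical_channels_reach_pixel_bound(self, rng):
        line = rng.standard_normal(30)
        samples = np.tile(line[:, None, None], (1, 8, 3))
        data = ChannelData(
            samples=samples,
            meta=FrameMeta(n_channels=8, center_freq_hz=5e6, sampling_freq_hz=20e6),
        )
        img = slsc_image_cpu(data, SLSCParams(kernel_len=7, short_lag=6))
        np.testing.assert_allclose(img.pixels, 6.0, atol=1e-10)

    def test_independent_noise_near_zero_mean(self, rng):
        samples = rng.standard_normal((120, 16, 8))
        data = ChannelData(
            samples=samples,
            meta=FrameMeta(n_channels=16, center_freq_hz=5e6, sampling_freq_hz=20e6),
        )
        params = SLSCParams(short_lag=10)
        img = slsc_image_cpu(data, params)
        assert abs(img.pixels.mean()) < 0.05 * params.short_lag

    def test_pixel_bound(self, speckle_frame):
        params = SLSCParams()
        img = slsc_image_cpu(speckle_frame, params)
        assert np.all(np.abs(img.pixels) <= params.short_lag + 1e-9)

    def test_too_few_axial_samples(self, rng):
        data = ChannelData(
            samples=rng.standard_normal((5, 8, 2)),
            meta=FrameMeta(n_channels=8, center_freq_hz=5e6, sampling_freq_hz=20e6),
        )
        with pytest.raises(ValueError):
            slsc_image_cpu(data, SLSCParams(kernel_len=7))


class TestSlscImageGpuStyle:
    def test_identical_channels_normalization_cancels(self, rng):
        line = rng.standard_normal(30)
        samples = np.tile(line[:, None, None], (1, 8, 3))
        data = ChannelData(
            samples=samples,
            meta=FrameMeta(n_channels=8, center_freq_hz=5e6, sampling_freq_hz=20e6),
        )
        img = slsc_image_gpu_style(data, SLSCParams(kernel_len=7, short_lag=6))
        np.testing.assert_allclose(img.pixels, 6.0, atol=1e-10)

    def test_kernel_length_one_is_pure_single_sample(self, rng):
        samples = rng.standard_normal((12, 6, 2))
        data = ChannelData(
            samples=samples,
            meta=FrameMeta(n_channels=6, center_freq_hz=5e6, sampling_freq_hz=20e6),
        )
        img = slsc_image_gpu_style(data, SLSCParams(kernel_len=1, short_lag=3, edge_skip=0))
        n = 6
        expected = np.zeros((12, 2))
        for m in range(1, 4):
            for a in range(12):
                for l in range(2):
                    x = samples[a, :, l]
                    num = float(np.dot(x[: n - m], x[m:]))
                    den = np.sqrt(np.sum(x[: n - m] ** 2)) * np.sqrt(np.sum(x[m:] ** 2))
                    expected[a, l] += num / den
        np.testing.assert_allclose(img.pixels, expected, atol=1e-12)

    def test_approximates_but_differs_from_reference(self, speckle_frame):
        from coherenet import image_correlation

        params = SLSCParams()
        cpu = slsc_image_cpu(speckle_frame, params)
        gpu = slsc_image_gpu_style(speckle_frame, params)
        assert cpu.pixels.shape == gpu.pixels.shape
        corr = image_correlation(gpu.pixels, cpu.pixels)
        assert 0.5 < corr < 1.0


class TestDas:
    def _data(self, samples):
        return ChannelData(
            samples=samples,
            meta=FrameMeta(
                n_channels=samples.shape[1], center_freq_hz=5e6, sampling_freq_hz=20e6
            ),
        )

    def test_all_zero_stays_zero(self):
        img = das_image(self._data(np.zeros((16, 4, 2))))
        np.testing.assert_array_equal(img, np.zeros((16, 2)))

    def test_single_channel_envelope(self, rng):
        import scipy.signal

        samples = np.zeros((64, 4, 1))
        samples[:, 2, 0] = np.sin(2 * np.pi * 0.1 * np.arange(64))
        img = das_image(self._data(samples))
        env = np.abs(scipy.signal.hilbert(samples[:, 2, 0]))
        np.testing.assert_allclose(img[:, 0], env / env.max(), atol=1e-12)

    def test_channel_sum_linearity(self, rng):
        one = np.zeros((64, 8, 1))
        one[:, 0, 0] = np.sin(2 * np.pi * 0.1 * np.arange(64))
        all_ch = np.tile(one[:, :1, :], (1, 8, 1))
        img_one = das_image(self._data(one))
        img_all = das_image(self._data(all_ch))
        # N identical channels scale the pre-envelope sum by N, which the
        # per-image normalization removes again.
        np.testing.assert_allclose(img_all, img_one, atol=1e-12)


class TestResample:
    def test_identity_factor(self, speckle_frame):
        out = resample_channel_data(speckle_frame, 1)
        np.testing.assert_array_equal(out.samples, speckle_frame.samples)

    def test_shape_arithmetic(self, rng):
        data = ChannelData(
            samples=rng.standard_normal((200, 64, 128)),
            meta=FrameMeta(n_channels=64, center_freq_hz=5e6, sampling_freq_hz=40e6),
        )
        half = resample_channel_data(data, 0.5)
        assert half.samples.shape == (100, 64, 64)
        assert half.meta.sampling_freq_hz == 20e6
        double = resample_channel_data(data, 2)
        assert double.samples.shape == (400, 64, 256)

    def test_round_trip_on_smooth_signal(self):
        ax = np.sin(2 * np.pi * 0.02 * np.arange(128))
        samples = np.tile(ax[:, None, None], (1, 4, 6))
        data = ChannelData(
            samples=samples,
            meta=FrameMeta(n_channels=4, center_freq_hz=5e6, sampling_freq_hz=40e6),
        )
        back = resample_channel_data(resample_channel_data(data, 0.5), 2)
        assert back.samples.shape == samples.shape
        # interior only: the final sample is flat-extrapolated
        assert np.max(np.abs(back.samples[:-2] - samples[:-2])) < 0.02

    def test_too_aggressive_downsampling(self, rng):
        data = ChannelData(
            samples=rng.standard_normal((4, 4, 8)),
            meta=FrameMeta(n_channels=4, center_freq_hz=5e6, sampling_freq_hz=40e6),
        )
        with pytest.raises(ValueError):
            resample_channel_data(data, 0.1)
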