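"""Spectral front end: closed forms, FFT oracles, filterbank invariants."""

import numpy as np
import pytest

from melcrnn.errors import ConfigError, ValidationError
from melcrnn.spectral import (ComplexSpectrogram, SpectralConfig, conv_stft,
                              dft_kernels, extract_features, hz_to_mel, log_mel,
                              make_window, mel_filterbank, mel_to_hz,
                              power_spectrogram)


def reference_stft_power(x, n_fft, hop, window):
    """Independent STFT oracle: per-frame windowed rfft, no padding/centering."""
    frames = np.lib.stride_tricks.sliding_window_view(x, n_fft)[::hop]
    return np.abs(np.fft.rfft(frames * window, axis=1).T) ** 2


class TestWindow:
    def test_hann_closed_forms(self):
        w = make_window(50, "hann")
        assert w[0] == 0.0
        assert w[25] == 1.0
        assert abs(w.sum() - 25.0) < 1e-12  # periodic Hann sums to N/2
        assert np.all((w >= 0) & (w <= 1))

    def test_rect_is_ones(self):
        np.testing.assert_array_equal(make_window(8, "rect"), np.ones(8))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_window(1)


class TestDFTKernels:
    def test_shapes_at_default_config(self):
        k = dft_kernels(SpectralConfig())
        assert k.real_kernel.shape == (26, 50)
        assert k.imag_kernel.shape == (26, 50)

    def test_dc_row_with_rect_window(self):
        k = dft_kernels(SpectralConfig(n_fft=16, window="rect", n_mels=5))
        np.testing.assert_allclose(k.real_kernel[0], 1.0)
        np.testing.assert_allclose(k.imag_kernel[0], 0.0, atol=1e-15)

    def test_rows_match_dft_matrix(self):
        """Every kernel row equals the conjugated DFT basis row."""
        n = 16
        k = dft_kernels(SpectralConfig(n_fft=n, window="rect", n_mels=5))
        dft = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        np.testing.assert_allclose(k.real_kernel, dft[: n // 2 + 1].real, atol=1e-12)
        np.testing.assert_allclose(k.imag_kernel, dft[: n // 2 + 1].imag, atol=1e-12)


class TestConvSTFT:
    def test_frame_count_matches_patch_arithmetic(self):
        cfg = SpectralConfig()  # N=50, hop=1
        x = np.random.default_rng(0).standard_normal(200)
        c = conv_stft(x, dft_kernels(cfg), cfg.hop)
        assert c.real_part.shape == (26, 151)

    def test_zero_signal_gives_zero_spectrogram(self):
        cfg = SpectralConfig(n_fft=16, n_mels=5)
        c = conv_stft(np.zeros(64), dft_kernels(cfg), hop=4)
        assert not c.real_part.any() and not c.imag_part.any()

    def test_matches_direct_dft_per_frame(self):
        cfg = SpectralConfig(n_fft=20, hop=3, n_mels=5)
        rng = np.random.default_rng(42)
        x = rng.standard_normal(100)
        c = conv_stft(x, dft_kernels(cfg), cfg.hop)
        w = make_window(20)
        for t in [0, 5, 26]:
            frame = x[t * 3 : t * 3 + 20] * w
            ref = np.fft.rfft(frame)
            np.testing.assert_allclose(c.real_part[:, t], ref.real, atol=1e-9)
            np.testing.assert_allclose(c.imag_part[:, t], ref.imag, atol=1e-9)

    def test_short_signal_rejected(self):
        cfg = SpectralConfig(n_fft=50)
        with pytest.raises(ValueError):
            conv_stft(np.zeros(30), dft_kernels(cfg), 1)

    @pytest.mark.parametrize("n_fft,hop", [(16, 1), (16, 5), (50, 1), (50, 5)])
    def test_power_matches_fft_oracle(self, n_fft, hop, rng):
        for _ in range(5):
            length = rng.integers(64, 512)
            x = rng.standard_normal(length)
            cfg = SpectralConfig(n_fft=n_fft, hop=hop, n_mels=5)
            p = power_spectrogram(conv_stft(x, dft_kernels(cfg), hop))
            ref = reference_stft_power(x, n_fft, hop, make_window(n_fft))
            err = np.abs(p - ref).max() / ref.max()
            assert err < 1e-6

    def test_parseval_energy_identity(self, rng):
        """Rect window, hop=N: doubled interior bins recover N * sum(x^2) per frame."""
        n = 16
        cfg = SpectralConfig(n_fft=n, hop=n, window="rect", n_mels=5)
        x = rng.standard_normal(5 * n)
        p = power_spectrogram(conv_stft(x, dft_kernels(cfg), n))
        frames = x.reshape(5, n)
        for t in range(5):
            total = p[0, t] + p[n // 2, t] + 2 * p[1 : n // 2, t].sum()
            np.testing.assert_allclose(total, n * (frames[t] ** 2).sum(), rtol=1e-6)

    def test_sinusoid_at_bin_frequency_peaks_there(self):
        n, k0 = 64, 12
        cfg = SpectralConfig(n_fft=n, window="rect", n_mels=5)
        t = np.arange(4 * n)
        x = np.sin(2 * np.pi * k0 * t / n)
        p = power_spectrogram(conv_stft(x, dft_kernels(cfg), hop=7))
        assert (p.argmax(axis=0) == k0).all()


class TestMelScale:
    def test_closed_form_values(self):
        assert hz_to_mel(0.0) == 0.0
        assert abs(hz_to_mel(6300.0) - 2595.0) < 1e-9
        assert abs(hz_to_mel(700.0) - 2595.0 * np.log10(2.0)) < 1e-9

    def test_strictly_monotone_and_invertible(self):
        f = np.linspace(0, 500, 200)
        m = hz_to_mel(f)
        assert np.all(np.diff(m) > 0)
        np.testing.assert_allclose(mel_to_hz(m), f, atol=1e-9)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_mel(-1.0)


class TestMelFilterbank:
    def test_shape_and_peaks_at_operating_point(self):
        fb = mel_filterbank(SpectralConfig())
        assert fb.weights.shape == (12, 26)
        # each triangle peaks at exactly 1 at its center bin and only there
        for m in range(12):
            row = fb.weights[m]
            assert row.max() == 1.0
            assert (row == 1.0).sum() == 1
            assert row.argmax() == fb.center_bins[m + 1]

    def test_compact_support(self):
        fb = mel_filterbank(SpectralConfig())
        for m in range(fb.n_mels):
            row = fb.weights[m]
            left, right = fb.center_bins[m], fb.center_bins[m + 2]
            k = np.arange(fb.n_bins)
            outside = (k < left) | (k > right)
            assert not row[outside].any()
            assert row[fb.center_bins[m]] == 0.0 or fb.center_bins[m] == 0
            assert row[right] == 0.0

    def test_weights_bounded(self):
        fb = mel_filterbank(SpectralConfig(n_fft=64, n_mels=20))
        assert np.all((fb.weights >= 0) & (fb.weights <= 1))

    def test_too_many_filters_rejected(self):
        with pytest.raises(ConfigError):
            mel_filterbank(SpectralConfig(n_fft=8, n_mels=5))


class TestLogMel:
    def test_db_closed_forms(self):
        cfg = SpectralConfig()
        fb = mel_filterbank(cfg)
        # craft a power spectrogram whose Mel output hits chosen values:
        # filters peak at 1 so feeding the center bins isolates scaling
        p = np.zeros((26, 3))
        m0 = fb.center_bins[1]
        p[m0, 0] = 1.0    # MS == ref -> 0 dB
        p[m0, 1] = 10.0   # one decade -> 10 dB
        out = log_mel(p, fb, cfg)
        assert abs(out[0, 0] - 0.0) < 1e-9
        assert abs(out[0, 1] - 10.0) < 1e-9
        assert abs(out[0, 2] - (-100.0)) < 1e-9  # floor: amin=1e-10, ref=1

    def test_monotone_in_power(self, rng):
        cfg = SpectralConfig()
        fb = mel_filterbank(cfg)
        p = rng.random((26, 4))
        base = log_mel(p, fb, cfg)
        boosted = log_mel(p * 2.0, fb, cfg)
        assert np.all(boosted >= base)

    def test_bin_mismatch_rejected(self):
        cfg = SpectralConfig()
        fb = mel_filterbank(cfg)
        with pytest.raises(ValidationError):
            log_mel(np.ones((20, 4)), fb, cfg)


class TestExtractFeatures:
    def test_default_shapes(self, rng):
        patch = rng.standard_normal((17, 200))
        out = extract_features(patch, SpectralConfig())
        assert out.shape == (17, 12, 151)

    def test_zero_patch_hits_floor(self):
        cfg = SpectralConfig()
        out = extract_features(np.zeros((2, 200)), cfg)
        np.testing.assert_allclose(out, -100.0)

    def test_channels_are_independent(self, rng):
        cfg = SpectralConfig(n_fft=16, hop=4, n_mels=5)
        patch = rng.standard_normal((3, 80))
        full = extract_features(patch, cfg)
        for ch in range(3):
            single = extract_features(patch[ch : ch + 1], cfg)
            np.testing.assert_array_equal(full[ch], single[0])

    def test_channel_permutation_equivariance(self, rng):
        cfg = SpectralConfig(n_fft=16, hop=4, n_mels=5)
        patch = rng.standard_normal((4, 64))
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_array_equal(
            extract_features(patch[perm], cfg), extract_features(patch, cfg)[perm])


def test_config_validation():
    with pytest.raises(ConfigError):
        SpectralConfig(n_fft=51)  # odd
    with pytest.raises(ConfigError):
        SpectralConfig(hop=0)
    with pytest.raises(ConfigError):
        SpectralConfig(n_mels=40)  # > n_fft/2 + 1
    with pytest.raises(ConfigError):
        SpectralConfig(f_min=300.0)  # >= f_max
    with pytest.raises(ConfigError):
        SpectralConfig(ref=0.0)


def test_complex_spectrogram_shape_check():
    with pytest.raises(ValidationError):
        ComplexSpectrogram(np.ones((3, 4)), np.ones((3, 5)))
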