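"""Extract log-Mel spectrogram features with the convolution-kernel STFT.

A 200-sample patch at 400 Hz passes through a 50-point windowed-DFT
convolution (hop 1), squaring, a 12-filter triangular Mel projection, and
dB conversion — giving a 12 x 151 time-frequency image per channel.
"""

import numpy as np

from melcrnn import (SpectralConfig, conv_stft, dft_kernels, extract_features,
                     mel_filterbank, power_spectrogram)

cfg = SpectralConfig()  # n_fft=50, hop=1, 12 Mel filters, 400 Hz
print(f"config: kernel {cfg.n_fft}, hop {cfg.hop}, {cfg.n_mels} Mel filters, "
      f"{cfg.rate:.0f} Hz -> {cfg.n_bins} frequency bins")

# a 10 Hz (alpha) tone plus noise on one channel
t = np.arange(200) / cfg.rate
rng = np.random.default_rng(0)
patch = (6 * np.sin(2 * np.pi * 10 * t) + rng.standard_normal(200))[None, :]

kernel = dft_kernels(cfg)
spec = conv_stft(patch[0], kernel, cfg.hop)
power = power_spectrogram(spec)
print(f"power spectrogram: {power.shape} (bins x frames); "
      f"peak bin {power.mean(axis=1).argmax()} "
      f"= {power.mean(axis=1).argmax() * cfg.rate / cfg.n_fft:.0f} Hz")

fb = mel_filterbank(cfg)
print(f"Mel filterbank: {fb.weights.shape}, each row peaks at 1.0")

features = extract_features(patch, cfg)
print(f"log-Mel features: {features.shape} (channels x mel x frames), "
      f"range [{features.min():.1f}, {features.max():.1f}] dB")
mel_profile = features[0].mean(axis=1)
print(f"most energetic Mel band: {mel_profile.argmax()} "
      "(low bands cover the alpha range, matching the 10 Hz tone)")
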