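"""Spectral feature extraction: convolution-kernel STFT and log-Mel spectrograms.

The short-time Fourier transform is expressed as a strided 1-D convolution
whose kernels are rows of the (truncated) DFT matrix multiplied by the
analysis window:

    real_kernel[k, n] =  cos(2*pi*k*n/N) * w[n]
    imag_kernel[k, n] = -sin(2*pi*k*n/N) * w[n],   k = 0 .. N/2

so that convolving a real signal with both kernel stacks at hop S yields the
real/imaginary parts of the STFT with no padding or frame centering.  Because
the transform is a plain convolution, the kernels can also serve as the
*initialisation* of a trainable front-end layer (see ``melcrnn.model``).

The Mel stage projects the power spectrogram through a bank of triangular
filters spaced uniformly on the Mel scale, Mel(f) = 2595*log10(1 + f/700),
and converts to decibels relative to a reference power:

    LogMel = 10*log10(max(M @ P, amin)) - 10*log10(ref).

Filters are *not* area-normalised: each triangle peaks at exactly 1 at its
center bin and is zero outside its two neighbouring center bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ConfigError, ValidationError

__all__ = [
    "SpectralConfig",
    "DFTKernel",
    "ComplexSpectrogram",
    "MelFilterbank",
    "make_window",
    "dft_kernels",
    "conv_stft",
    "power_spectrogram",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "log_mel",
    "extract_features",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Settings of the STFT + log-Mel front end.

    Defaults follow the pipeline's tuned operating point: transform size
    (= 1-D convolution kernel size) 50 samples, hop 1 sample, 12 Mel
    filters, at a 400 Hz working sampling rate.

    Parameters
    ----------
    n_fft : transform/kernel size N in samples (even, >= 2).
    hop : frame step S in samples.
    window : analysis window, periodic Hann or rectangular.
    rate : working sampling rate in Hz (after any resampling).
    n_mels : number of triangular Mel filters.
    f_min, f_max : Mel filterbank frequency range in Hz; ``f_max=None``
        means the Nyquist frequency rate/2.
    ref : dB reference power; the float reference, or ``"max"`` to
        reference each patch to its maximum Mel power.
    amin : power floor guarding ``log10(0)``.
    trainable_kernels : whether a model built from this config treats the
        STFT kernels as trainable parameters (initialised from the DFT)
        or keeps them frozen.
    """

    n_fft: int = 50
    hop: int = 1
    window: Literal["hann", "rect"] = "hann"
    rate: float = 400.0
    n_mels: int = 12
    f_min: float = 0.0
    f_max: float | None = None
    ref: float | Literal["max"] = 1.0
    amin: float = 1e-10
    trainable_kernels: bool = True

    def __post_init__(self):
        if self.n_fft < 2 or self.n_fft % 2 != 0:
            raise ConfigError(f"n_fft must be even and >= 2, got {self.n_fft}")
        if self.hop < 1:
            raise ConfigError(f"hop must be >= 1, got {self.hop}")
        if self.rate <= 0:
            raise ConfigError(f"rate must be positive, got {self.rate}")
        if not 1 <= self.n_mels <= self.n_fft // 2 + 1:
            raise ConfigError(
                f"n_mels must be in [1, n_fft/2 + 1] = [1, {self.n_fft // 2 + 1}], got {self.n_mels}"
            )
        fmax = self.rate / 2 if self.f_max is None else self.f_max
        if not 0 <= self.f_min < fmax <= self.rate / 2:
            raise ConfigError(
                f"need 0 <= f_min < f_max <= rate/2, got f_min={self.f_min}, f_max={fmax}"
            )
        if self.ref != "max" and self.ref <= 0:
            raise ConfigError(f"ref must be positive or 'max', got {self.ref}")
        if self.amin <= 0:
            raise ConfigError(f"amin must be positive, got {self.amin}")

    @property
    def n_bins(self) -> int:
        return self.n_fft // 2 + 1

    @property
    def effective_f_max(self) -> float:
        return self.rate / 2 if self.f_max is None else self.f_max

    def n_frames(self, length: int) -> int:
        """Frame count for a signal of ``length`` samples (no padding)."""
        if length < self.n_fft:
            raise ValueError(f"signal length {length} < n_fft {self.n_fft}")
        return (length - self.n_fft) // self.hop + 1

    def with_(self, **kwargs) -> "SpectralConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DFTKernel:
    """Truncated windowed DFT basis, ready to act as convolution kernels."""

    real_kernel: np.ndarray  # (n_bins, n_fft)
    imag_kernel: np.ndarray  # (n_bins, n_fft)
    window_applied: bool

    @property
    def n_bins(self) -> int:
        return self.real_kernel.shape[0]

    @property
    def n_fft(self) -> int:
        return self.real_kernel.shape[1]


@dataclass(frozen=True)
class ComplexSpectrogram:
    real_part: np.ndarray  # (n_bins, n_frames)
    imag_part: np.ndarray

    def __post_init__(self):
        if self.real_part.shape != self.imag_part.shape:
            raise ValidationError(
                f"real/imag shape mismatch: {self.real_part.shape} vs {self.imag_part.shape}"
            )


@dataclass(frozen=True)
class MelFilterbank:
    """Triangular filters mapping linear-frequency bins to Mel bins."""

    weights: np.ndarray  # (n_mels, n_bins), values in [0, 1]
    center_bins: np.ndarray = field(repr=False, default=None)  # (n_mels + 2,) bin indices

    @property
    def n_mels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]


def make_window(n_fft: int, kind: str = "hann") -> np.ndarray:
    """Analysis window of length ``n_fft``.

    ``hann`` is the periodic form w[k] = (1 - cos(2*pi*k/N)) / 2, k = 0..N-1,
    which sums to N/2; ``rect`` is all ones.
    """
    if n_fft < 2:
        raise ValueError(f"n_fft must be >= 2, got {n_fft}")
    if kind == "hann":
        k = np.arange(n_fft)
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n_fft))
    if kind == "rect":
        return np.ones(n_fft)
    raise ValueError(f"unknown window kind {kind!r}; choose 'hann' or 'rect'")


def dft_kernels(cfg: SpectralConfig) -> DFTKernel:
    """Windowed DFT convolution kernels for the first N/2 + 1 frequency bins."""
    n = cfg.n_fft
    w = make_window(n, cfg.window)
    k = np.arange(cfg.n_bins)[:, None]
    t = np.arange(n)[None, :]
    angle = 2.0 * np.pi * k * t / n
    return DFTKernel(
        real_kernel=np.cos(angle) * w,
        imag_kernel=-np.sin(angle) * w,
        window_applied=True,
    )


def frame_signal(signal: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Strided frames (n_frames, n_fft) of a 1-D signal; no padding."""
    signal = np.asarray(signal)
    if signal.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {signal.shape}")
    if signal.shape[0] < n_fft:
        raise ValueError(f"signal length {signal.shape[0]} < n_fft {n_fft}")
    frames = np.lib.stride_tricks.sliding_window_view(signal, n_fft)[::hop]
    return frames


def conv_stft(signal: np.ndarray, kernel: DFTKernel, hop: int = 1) -> ComplexSpectrogram:
    """STFT of one channel as a strided convolution with the DFT kernels.

    Frame t, bin k equals sum_n signal[t*hop + n] * kernel[k, n]; frames are
    fully inside the signal (no centering), so
    n_frames = floor((L - n_fft)/hop) + 1.
    """
    frames = frame_signal(signal, kernel.n_fft, hop)
    return ComplexSpectrogram(
        real_part=kernel.real_kernel @ frames.T,
        imag_part=kernel.imag_kernel @ frames.T,
    )


def power_spectrogram(c: ComplexSpectrogram) -> np.ndarray:
    """Elementwise power real^2 + imag^2, shape (n_bins, n_frames)."""
    return c.real_part**2 + c.imag_part**2


def hz_to_mel(f):
    """Mel(f) = 2595 * log10(1 + f/700); strictly increasing, Mel(0) = 0."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    m = np.asarray(m, dtype=float)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(cfg: SpectralConfig) -> MelFilterbank:
    """Triangular Mel filterbank over the STFT bins.

    n_mels + 2 points are spaced uniformly on the Mel scale between f_min and
    f_max, mapped back to Hz and then to the nearest STFT bin index.  Filter m
    rises linearly from bin point m-1 to exactly 1 at point m and falls to 0 at
    point m+1.  Coincident rounded centers are pushed right by one bin so that
    the points stay strictly increasing (triangles need distinct corners).
    """
    mel_lo = hz_to_mel(cfg.f_min)
    mel_hi = hz_to_mel(cfg.effective_f_max)
    mel_pts = np.linspace(mel_lo, mel_hi, cfg.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.round(hz_pts * cfg.n_fft / cfg.rate).astype(int)
    for i in range(1, len(bins)):
        if bins[i] <= bins[i - 1]:
            bins[i] = bins[i - 1] + 1
    if bins[-1] > cfg.n_bins - 1:
        raise ConfigError(
            f"{cfg.n_mels} Mel filters do not fit in {cfg.n_bins} STFT bins with "
            f"distinct centers; reduce n_mels or increase n_fft"
        )
    k = np.arange(cfg.n_bins)
    weights = np.zeros((cfg.n_mels, cfg.n_bins))
    for m in range(1, cfg.n_mels + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        up = (k - left) / (center - left)
        down = (right - k) / (right - center)
        weights[m - 1] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return MelFilterbank(weights=weights, center_bins=bins)


def _db(power: np.ndarray, ref, amin: float) -> np.ndarray:
    ref_val = power.max() if ref == "max" else float(ref)
    ref_val = max(ref_val, amin)
    return 10.0 * np.log10(np.maximum(power, amin)) - 10.0 * np.log10(ref_val)


def log_mel(power: np.ndarray, fb: MelFilterbank, cfg: SpectralConfig) -> np.ndarray:
    """Project a power spectrogram through the filterbank and convert to dB.

    Returns (n_mels, n_frames).  The output is bounded below by
    10*log10(amin) - 10*log10(ref).
    """
    power = np.asarray(power)
    if power.ndim != 2 or power.shape[0] != fb.n_bins:
        raise ValidationError(
            f"power spectrogram has {power.shape[0] if power.ndim == 2 else '?'} bins, "
            f"filterbank expects {fb.n_bins}"
        )
    ms = fb.weights @ power
    return _db(ms, cfg.ref, cfg.amin)


def extract_features(patch: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    """Log-Mel features of a multichannel patch.

    Parameters
    ----------
    patch : (n_channels, patch_len) array at the working rate.

    Returns
    -------
    (n_channels, n_mels, n_frames) array of dB values; channels are
    processed independently.
    """
    patch = np.atleast_2d(np.asarray(patch, dtype=float))
    if patch.shape[1] < cfg.n_fft:
        raise ValueError(f"patch length {patch.shape[1]} < n_fft {cfg.n_fft}")
    kernel = dft_kernels(cfg)
    fb = mel_filterbank(cfg)
    n_frames = cfg.n_frames(patch.shape[1])
    out = np.empty((patch.shape[0], cfg.n_mels, n_frames))
    for ch in range(patch.shape[0]):
        c = conv_stft(patch[ch], kernel, cfg.hop)
        out[ch] = log_mel(power_spectrogram(c), fb, cfg)
    return out
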