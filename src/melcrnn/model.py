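"""The LogMel-CRNN vigilance classifier.

Architecture (per 1,600-sample segment, split into a sequence of eight
200-sample patches):

1. **Spectral front end** — the STFT as a 1-D convolution whose kernels are
   initialised from the windowed DFT basis (optionally trainable), followed
   by power, a fixed triangular Mel projection, and conversion to dB.  Each
   patch becomes an (n_channels, n_mels, n_frames) image.
2. **CNN** — three VGG-style blocks of [conv3x3 - BN - ReLU] x 2 followed by
   2x2 average pooling, with dropout (p=0.2) after each block; global
   average pooling turns each patch into a feature vector.
3. **BiRNN** — a two-layer bidirectional recurrent network (vanilla tanh
   cells by default, 128 hidden units per direction) over the 8-patch
   sequence; the terminal hidden states of both directions are concatenated.
4. **Classifier** — fully connected, ReLU, fully connected, softmax.

Ablation switches reproduce the reduced variants: ``frontend="power"``
bypasses the Mel projection (dB power spectrogram straight to the CNN),
``frontend="none"`` feeds raw waveform patches to the CNN, and
``use_rnn=False`` replaces the recurrent stage by the mean of the eight CNN
vectors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np

from .errors import ConfigError, ValidationError
from .nn.autograd import Tensor, concat
from .nn.layers import (AvgPool2d, BatchNorm2d, BiRNN, Conv2d, Dropout, Linear,
                        Module, Parameter)
from .nn.optim import softmax
from .spectral import SpectralConfig, dft_kernels, mel_filterbank

__all__ = ["ModelConfig", "LogMelCRNN", "build_model", "xavier_init",
           "save_checkpoint", "load_checkpoint"]

_LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class ModelConfig:
    """Structure of the network.

    ``conv_widths`` are the channel counts of the three conv blocks;
    ``fc_size`` is the width of the hidden fully connected layer of the
    classifier; ``n_classes`` is 2 (vigilant/fatigue) or 3 (+drowsy).
    """

    in_channels: int = 17
    conv_widths: tuple[int, int, int] = (64, 128, 256)
    dropout_p: float = 0.2
    rnn_layers: int = 2
    rnn_hidden: int = 128
    rnn_cell: Literal["elman_tanh", "gru", "lstm"] = "elman_tanh"
    fc_size: int = 128
    n_classes: int = 2
    frontend: Literal["logmel", "power", "none"] = "logmel"
    use_rnn: bool = True

    def __post_init__(self):
        if any(w < 1 for w in self.conv_widths) or len(self.conv_widths) != 3:
            raise ConfigError(f"conv_widths must be three ints >= 1, got {self.conv_widths}")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.in_channels < 1 or self.rnn_layers < 1 or self.rnn_hidden < 1 or self.fc_size < 1:
            raise ConfigError("in_channels, rnn_layers, rnn_hidden, fc_size must be >= 1")
        if self.frontend not in ("logmel", "power", "none"):
            raise ConfigError(f"unknown frontend {self.frontend!r}")


class _ConvBlock(Module):
    def __init__(self, c_in: int, c_out: int, p_drop: float):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out)
        self.bn2 = BatchNorm2d(c_out)
        self.pool = AvgPool2d()
        self.drop = Dropout(p_drop)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        return self.drop(self.pool(x))


class LogMelCRNN(Module):
    """CNN + bidirectional RNN over log-Mel patch sequences."""

    def __init__(self, cfg: ModelConfig, spectral: SpectralConfig):
        super().__init__()
        self.cfg = cfg
        self.spectral = spectral
        if cfg.frontend != "none":
            kern = dft_kernels(spectral)
            real = kern.real_kernel.T.astype(np.float32)  # (n_fft, n_bins)
            imag = kern.imag_kernel.T.astype(np.float32)
            if spectral.trainable_kernels:
                self.k_real: Tensor = Parameter(real)
                self.k_imag: Tensor = Parameter(imag)
            else:
                self.k_real = Tensor(real)
                self.k_imag = Tensor(imag)
        if cfg.frontend == "logmel":
            fb = mel_filterbank(spectral)
            self.mel_weights = Tensor(fb.weights.T.astype(np.float32))  # (n_bins, n_mels)
        widths = cfg.conv_widths
        self.blocks = [
            _ConvBlock(cfg.in_channels, widths[0], cfg.dropout_p),
            _ConvBlock(widths[0], widths[1], cfg.dropout_p),
            _ConvBlock(widths[1], widths[2], cfg.dropout_p),
        ]
        if cfg.use_rnn:
            self.rnn = BiRNN(widths[2], cfg.rnn_hidden, cfg.rnn_layers, cfg.rnn_cell)
            clf_in = 2 * cfg.rnn_hidden
        else:
            self.rnn = None
            clf_in = widths[2]
        self.fc1 = Linear(clf_in, cfg.fc_size)
        self.fc2 = Linear(cfg.fc_size, cfg.n_classes)

    # -- initialisation ----------------------------------------------------
    def init_params(self, seed: int) -> "LogMelCRNN":
        """Xavier-normal weights, zero biases; DFT kernels reset to the DFT
        basis (their natural initialisation); dropout streams seeded."""
        rng = np.random.default_rng(seed)
        for block in self.blocks:
            block.conv1.init(rng)
            block.conv2.init(rng)
            block.bn1.weight.data[...] = 1.0
            block.bn1.bias.data[...] = 0.0
            block.bn2.weight.data[...] = 1.0
            block.bn2.bias.data[...] = 0.0
            block.bn1.running_mean[...] = 0.0
            block.bn1.running_var[...] = 1.0
            block.bn2.running_mean[...] = 0.0
            block.bn2.running_var[...] = 1.0
        if self.rnn is not None:
            self.rnn.init(rng)
        self.fc1.init(rng)
        self.fc2.init(rng)
        if self.cfg.frontend != "none":
            kern = dft_kernels(self.spectral)
            self.k_real.data[...] = kern.real_kernel.T
            self.k_imag.data[...] = kern.imag_kernel.T
        for m in self.modules():
            if isinstance(m, Dropout):
                m.seed(np.random.default_rng(rng.integers(2**31)))
        return self

    # -- forward ------------------------------------------------------------
    def _frontend(self, patches: np.ndarray) -> Tensor:
        """(B, P, C, L) raw patches -> channels-last (B*P, H, W, C) CNN input."""
        b, p, c, length = patches.shape
        cfg, sp = self.cfg, self.spectral
        if cfg.frontend == "none":
            img = patches.reshape(b * p, c, length).transpose(0, 2, 1)[:, None, :, :]
            return Tensor(np.ascontiguousarray(img, dtype=np.float32))
        if length < sp.n_fft:
            raise ValidationError(f"patch length {length} < n_fft {sp.n_fft}")
        flat = patches.reshape(b * p * c, length)
        frames = np.lib.stride_tricks.sliding_window_view(flat, sp.n_fft, axis=1)[:, :: sp.hop]
        t = frames.shape[1]
        frames_t = Tensor(np.ascontiguousarray(frames, dtype=np.float32).reshape(-1, sp.n_fft))
        real = frames_t @ self.k_real  # (BPC*T, n_bins)
        imag = frames_t @ self.k_imag
        power = real.square() + imag.square()
        if cfg.frontend == "logmel":
            power = power @ self.mel_weights  # (BPC*T, n_mels)
        if sp.ref == "max":
            per_patch = power.data.reshape(b * p * c, -1).max(axis=1)
            ref_val = np.repeat(np.maximum(per_patch, sp.amin), t)[:, None]
        else:
            ref_val = float(sp.ref)
        db = power.clamp_min(sp.amin).log() * (10.0 / _LN10) - Tensor(
            10.0 * np.log10(np.asarray(ref_val, dtype=np.float32)))
        img = db.reshape(b * p, c, t, db.shape[1]).transpose(0, 3, 2, 1)
        return img  # (B*P, n_mels | n_bins, n_frames, C)

    def forward(self, patches: np.ndarray) -> Tensor:
        """Logits (B, n_classes) for a batch of raw patch sequences (B, P, C, L)."""
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim != 4:
            raise ValidationError(
                f"expected patches of shape (batch, n_patches, n_channels, patch_len), "
                f"got {patches.shape}")
        if patches.shape[2] != self.cfg.in_channels:
            raise ValidationError(
                f"channel axis has size {patches.shape[2]}, model expects "
                f"{self.cfg.in_channels}")
        b, p = patches.shape[:2]
        x = self._frontend(patches)
        if min(x.shape[1], x.shape[2]) < 1:
            raise ConfigError("spatial input collapsed below 1x1 before the CNN")
        for block in self.blocks:
            x = block(x)
        x = x.mean(axis=(1, 2))  # (B*P, width)
        feats = x.reshape(b, p, x.shape[1])
        if self.rnn is not None:
            seq = [feats[:, t, :] for t in range(p)]
            out = self.rnn(seq)
            h = self.cfg.rnn_hidden
            final = concat([out[-1][:, :h], out[0][:, h:]], axis=1)
        else:
            final = feats.mean(axis=1)
        return self.fc2(self.fc1(final).relu())

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Evaluation-mode class probabilities (rows sum to 1)."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(np.asarray(patches))
        finally:
            if was_training:
                self.train()
        return softmax(logits.data)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(cfg: ModelConfig, spectral: SpectralConfig | None = None) -> LogMelCRNN:
    """Construct an (uninitialised) model; call ``xavier_init`` before use."""
    return LogMelCRNN(cfg, spectral or SpectralConfig())


def xavier_init(model: LogMelCRNN, seed: int) -> LogMelCRNN:
    """Seeded Xavier-normal initialisation of all weights (biases zero)."""
    return model.init_params(seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: LogMelCRNN, path) -> None:
    """Single-file archive of parameters, batch-norm statistics and config."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    for i, m in enumerate(m for m in model.modules() if isinstance(m, BatchNorm2d)):
        arrays[f"bn_mean_{i}"] = m.running_mean
        arrays[f"bn_var_{i}"] = m.running_var
    meta = {"model": asdict(model.cfg), "spectral": asdict(model.spectral)}
    arrays["config_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> LogMelCRNN:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["config_json"].tobytes()).decode())
        cfg = ModelConfig(**{**meta["model"],
                             "conv_widths": tuple(meta["model"]["conv_widths"])})
        spectral = SpectralConfig(**meta["spectral"])
        model = LogMelCRNN(cfg, spectral)
        for i, p in enumerate(model.parameters()):
            p.data[...] = npz[f"param_{i}"]
        bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
        for i, m in enumerate(bns):
            m.running_mean[...] = npz[f"bn_mean_{i}"]
            m.running_var[...] = npz[f"bn_var_{i}"]
    return model
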