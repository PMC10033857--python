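"""Synthetic EEG + PERCLOS fixture generator.

Emulates the spectral signature that separates vigilance states in real
driving-fatigue EEG: alert activity carries relatively strong beta
(13-30 Hz) and weak alpha/theta power, while fatigued/drowsy activity shows
elevated alpha (8-13 Hz) and theta (4-8 Hz) with depressed beta.  Each
channel is a sum of band-limited sinusoids (one per band, frequency drawn
uniformly inside the band per channel, random phase) whose amplitudes follow
the active state, on top of 1/f ("pink") background noise plus white sensor
noise.  A PERCLOS trace is sampled once per second around a per-state mean.

This is a *statistical stand-in*, not physiological EEG: there is no volume
conduction, no inter-channel correlation structure, and no ocular/muscle
artifacts.  It exists so that segmentation, feature extraction, training and
evaluation are exercisable end-to-end with controllable class separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import Recording, resample
from .labeling import LabelScheme, PerclosTrace, Segment, build_dataset
from .spectral import SpectralConfig

__all__ = ["BANDS", "SyntheticSpec", "EasyPreset", "generate_recording", "easy_preset"]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Per-state sinusoid amplitudes (microvolts) for each EEG band.  Alert EEG
#: has beta 3x the fatigued level; fatigued EEG has alpha 3x the alert level.
DEFAULT_BAND_POWER: dict[str, dict[str, float]] = {
    "vigilant": {"delta": 2.0, "theta": 2.0, "alpha": 2.0, "beta": 6.0},
    "fatigue": {"delta": 2.0, "theta": 5.0, "alpha": 6.0, "beta": 2.0},
    "drowsy": {"delta": 3.0, "theta": 6.0, "alpha": 8.0, "beta": 1.0},
}

#: Mean and jitter (1 s.d.) of the simulated PERCLOS trace per state.
DEFAULT_PERCLOS: dict[str, tuple[float, float]] = {
    "vigilant": (0.15, 0.05),
    "fatigue": (0.50, 0.08),
    "drowsy": (0.85, 0.05),
}

_SEED_VIG_CHANNELS = (
    "CP1", "CP2", "P1", "PZ", "P2", "PO3", "POZ", "PO4", "O1", "OZ", "O2",
    "FT7", "FT8", "T7", "T8", "TP7", "TP8",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording."""

    n_channels: int = 17
    rate: float = 1000.0
    state_sequence: tuple[tuple[str, float], ...] = (("vigilant", 64.0), ("fatigue", 64.0))
    band_power: dict = field(default_factory=lambda: DEFAULT_BAND_POWER)
    pink_noise_scale: float = 3.0
    white_noise_scale: float = 1.0
    perclos_by_state: dict = field(default_factory=lambda: DEFAULT_PERCLOS)
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1 or self.rate <= 0:
            raise ValidationError("need n_channels >= 1 and rate > 0")
        if not self.state_sequence:
            raise ValidationError("state_sequence must not be empty")
        for state, dur in self.state_sequence:
            if dur <= 0:
                raise ValidationError(f"state {state!r} has non-positive duration {dur}")
            if state not in self.band_power:
                raise ValidationError(f"state {state!r} has no band_power entry")
            if state not in self.perclos_by_state:
                raise ValidationError(f"state {state!r} has no perclos_by_state entry")
        for state, (mean, jitter) in self.perclos_by_state.items():
            if not 0 <= mean <= 1 or jitter < 0:
                raise ValidationError(f"bad PERCLOS spec for {state!r}: ({mean}, {jitter})")
        if self.pink_noise_scale < 0 or self.white_noise_scale < 0:
            raise ValidationError("noise scales must be >= 0")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.state_sequence))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = np.inf  # kill DC
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def generate_recording(spec: SyntheticSpec) -> tuple[Recording, PerclosTrace, np.ndarray]:
    """Generate one recording, its PERCLOS trace, and per-second state labels.

    Returns
    -------
    (Recording, PerclosTrace, states) where ``states`` is an array of state
    names, one per whole second.  The same spec (same seed) reproduces
    identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate

    # piecewise-constant per-band amplitude profile following the state sequence
    edges = np.cumsum([0.0] + [d for _, d in spec.state_sequence])
    state_of_sample = np.empty(n, dtype=object)
    amp = {band: np.empty(n) for band in BANDS}
    for (state, _), lo, hi in zip(spec.state_sequence, edges[:-1], edges[1:]):
        i0, i1 = int(round(lo * spec.rate)), min(int(round(hi * spec.rate)), n)
        state_of_sample[i0:i1] = state
        for band in BANDS:
            amp[band][i0:i1] = spec.band_power[state].get(band, 0.0)

    names = (_SEED_VIG_CHANNELS if spec.n_channels == len(_SEED_VIG_CHANNELS)
             else tuple(f"CH{i + 1}" for i in range(spec.n_channels)))
    data = np.zeros((spec.n_channels, n))
    for ch in range(spec.n_channels):
        x = np.zeros(n)
        for band, (f_lo, f_hi) in BANDS.items():
            freq = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0, 2 * np.pi)
            x += amp[band] * np.sin(2 * np.pi * freq * t + phase)
        if spec.pink_noise_scale > 0:
            x += spec.pink_noise_scale * _pink_noise(n, rng)
        if spec.white_noise_scale > 0:
            x += spec.white_noise_scale * rng.standard_normal(n)
        data[ch] = x

    seconds = np.arange(int(spec.duration))
    states = state_of_sample[(seconds * int(spec.rate)).clip(0, n - 1)]
    values = np.empty(len(seconds))
    for i, s in enumerate(states):
        mean, jitter = spec.perclos_by_state[s]
        values[i] = mean + jitter * rng.standard_normal()
    trace = PerclosTrace(times=seconds.astype(float), values=np.clip(values, 0.0, 1.0))
    rec = Recording(data=data, rate=spec.rate, channel_names=names)
    return rec, trace, states.astype(str)


@dataclass
class EasyPreset:
    """A ready-to-train synthetic dataset with large class separation."""

    segments: list[Segment]
    scheme: LabelScheme
    recording: Recording  # at the working rate
    trace: PerclosTrace
    spec: SyntheticSpec
    spectral_config: SpectralConfig
    states: np.ndarray


def easy_preset(seed: int, mode: str = "two_class", windows_per_class: int = 64,
                working_rate: float = 400.0, n_channels: int = 17,
                cfg: SpectralConfig | None = None) -> EasyPreset:
    """Strongly separable synthetic dataset sized for quick CPU training.

    Alternating state blocks of 8 windows each produce at least
    ``windows_per_class`` non-overlapping 1,600-sample windows per class at
    the working rate (4 s windows at 400 Hz).
    """
    scheme = LabelScheme(mode=mode)
    cfg = cfg or SpectralConfig(rate=working_rate)
    window_s = 1600 / working_rate
    block_s = 8 * window_s
    n_blocks = int(np.ceil(windows_per_class / 8))
    classes = list(scheme.class_names)
    sequence = []
    for i in range(n_blocks):
        for state in classes:
            sequence.append((state, block_s))
    spec = SyntheticSpec(
        n_channels=n_channels,
        rate=1000.0,
        state_sequence=tuple(sequence),
        seed=seed,
    )
    rec, trace, states = generate_recording(spec)
    rec = resample(rec, working_rate)
    segments = build_dataset(rec, trace, scheme, cfg=cfg, window_len=1600, patch_len=200)
    return EasyPreset(segments=segments, scheme=scheme, recording=rec, trace=trace,
                      spec=spec, spectral_config=cfg, states=states)
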