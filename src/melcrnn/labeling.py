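"""PERCLOS-based vigilance labeling and segmentation into model-ready data.

PERCLOS — the percentage of time the eyelids cover the pupil over an
interval — is the behavioural ground truth for vigilance:

    PERCLOS = (blink + CLOS) / (blink + fixation + saccade + CLOS)

Class boundaries: below 0.35 the driver is vigilant; from 0.35 the state is
fatigue; a three-class scheme adds drowsy at 0.7 and above.  A value exactly
on a threshold maps to the sleepier class (a total, deterministic rule).

Recordings are cut into non-overlapping sliding windows (1,600 samples at
the working rate by default) and each window into eight contiguous
200-sample patches, giving the 8-step sequence the recurrent model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, ValidationError
from .io import Recording
from .spectral import SpectralConfig, extract_features

__all__ = [
    "PerclosTrace",
    "LabelScheme",
    "Segment",
    "perclos",
    "label_from_perclos",
    "segment_recording",
    "split_patches",
    "build_dataset",
]


@dataclass(frozen=True)
class PerclosTrace:
    """Sampled eye-closure fraction over time: values in [0, 1] at ``times`` (s)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValidationError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(times) < 0):
            raise ValidationError("times must be nondecreasing")
        if np.any((values < 0) | (values > 1)):
            raise ValidationError("PERCLOS values must lie in [0, 1]")

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter="\t", header="time_s\tperclos")

    @classmethod
    def load(cls, path) -> "PerclosTrace":
        arr = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        return cls(times=arr[:, 0], values=arr[:, 1])


@dataclass(frozen=True)
class LabelScheme:
    """Two- or three-class vigilance labeling from PERCLOS thresholds."""

    mode: str = "two_class"
    thresholds: tuple[float, ...] = None
    class_names: tuple[str, ...] = None

    def __post_init__(self):
        if self.mode not in ("two_class", "three_class"):
            raise ConfigError(f"mode must be two_class or three_class, got {self.mode!r}")
        thr = self.thresholds
        if thr is None:
            thr = (0.35,) if self.mode == "two_class" else (0.35, 0.7)
        thr = tuple(float(t) for t in thr)
        expected = 1 if self.mode == "two_class" else 2
        if len(thr) != expected:
            raise ConfigError(f"{self.mode} needs {expected} threshold(s), got {thr}")
        if any(not 0 < t < 1 for t in thr) or list(thr) != sorted(set(thr)):
            raise ConfigError(f"thresholds must be strictly increasing inside (0,1): {thr}")
        names = self.class_names
        if names is None:
            names = ("vigilant", "fatigue") if self.mode == "two_class" else (
                "vigilant", "fatigue", "drowsy")
        if len(names) != expected + 1:
            raise ConfigError(f"{self.mode} needs {expected + 1} class names, got {names}")
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "class_names", tuple(names))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class Segment:
    """One labeled training example: an ordered sequence of patches.

    ``patches`` holds the raw waveform sequence (n_patches, n_channels,
    patch_len); ``features`` optionally caches the log-Mel transform
    (n_patches, n_channels, n_mels, n_frames).  ``span`` is the half-open
    [start, end) sample range in the source recording.
    """

    patches: np.ndarray
    label: int
    span: tuple[int, int]
    perclos: float = float("nan")
    features: Optional[np.ndarray] = field(default=None, repr=False)


def perclos(blink: float, fixation: float, saccade: float, clos: float) -> float:
    """Eye-closure fraction (blink + CLOS) / (blink + fixation + saccade + CLOS)."""
    durations = (blink, fixation, saccade, clos)
    if any(d < 0 for d in durations):
        raise ValueError(f"durations must be >= 0, got {durations}")
    interval = sum(durations)
    if interval == 0:
        raise ValueError("undefined interval: all four durations are zero")
    return (blink + clos) / interval


def label_from_perclos(v: float, scheme: LabelScheme) -> int:
    """Class index of a PERCLOS value; boundary values go to the sleepier class."""
    if not 0 <= v <= 1:
        raise ValueError(f"PERCLOS must be in [0, 1], got {v}")
    return int(np.searchsorted(scheme.thresholds, v, side="right"))


def segment_recording(rec: Recording, window_len: int = 1600,
                      stride: int | None = None) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut a recording into sliding windows.

    Returns a list of ((start, end), window) pairs, windows of shape
    (n_channels, window_len) at starts 0, stride, 2*stride, ...; a trailing
    partial window is dropped.  The default stride equals the window length
    (non-overlapping tiling).
    """
    if window_len < 1:
        raise ValueError(f"window_len must be >= 1, got {window_len}")
    stride = window_len if stride is None else stride
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if rec.n_samples < window_len:
        import warnings

        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{window_len}-sample window; no segments produced", stacklevel=2)
        return []
    out = []
    for start in range(0, rec.n_samples - window_len + 1, stride):
        out.append(((start, start + window_len), rec.data[:, start : start + window_len]))
    return out


def split_patches(window: np.ndarray, patch_len: int = 200) -> np.ndarray:
    """Split (n_channels, window_len) into (n_patches, n_channels, patch_len).

    Patches are contiguous, non-overlapping, in temporal order; the window
    length must be divisible by the patch length.
    """
    window = np.asarray(window)
    n_ch, window_len = window.shape
    if patch_len < 1 or window_len % patch_len != 0:
        raise ConfigError(
            f"window length {window_len} is not divisible by patch length {patch_len}")
    n_patches = window_len // patch_len
    return window.reshape(n_ch, n_patches, patch_len).transpose(1, 0, 2)


def window_perclos(trace: PerclosTrace, t_start: float, t_end: float) -> float:
    """Mean trace value inside [t_start, t_end); nearest sample if none fall inside."""
    inside = (trace.times >= t_start) & (trace.times < t_end)
    if inside.any():
        return float(trace.values[inside].mean())
    mid = 0.5 * (t_start + t_end)
    return float(trace.values[np.argmin(np.abs(trace.times - mid))])


def build_dataset(rec: Recording, trace: PerclosTrace, scheme: LabelScheme,
                  cfg: SpectralConfig | None = None, window_len: int = 1600,
                  patch_len: int = 200, stride: int | None = None,
                  with_features: bool = False) -> list[Segment]:
    """Assemble labeled segments from a recording and its PERCLOS trace.

    Each window becomes one :class:`Segment`: its PERCLOS is the mean of the
    trace values whose timestamps fall inside the window's time span, its
    label comes from ``scheme``, and (optionally) its log-Mel features are
    precomputed with ``cfg``.
    """
    if trace.times.size == 0:
        raise ValidationError("empty PERCLOS trace")
    t_span = (trace.times[0], trace.times[-1])
    if t_span[0] > 0 or t_span[1] < (rec.n_samples - 1) / rec.rate - 1.0:
        raise ValidationError(
            f"trace covers [{t_span[0]:.1f}, {t_span[1]:.1f}] s but the recording "
            f"spans [0.0, {rec.duration:.1f}] s")
    segments = []
    for (start, end), window in segment_recording(rec, window_len, stride):
        v = window_perclos(trace, start / rec.rate, end / rec.rate)
        patches = split_patches(window, patch_len)
        seg = Segment(
            patches=patches,
            label=label_from_perclos(v, scheme),
            span=(start, end),
            perclos=v,
        )
        if with_features:
            if cfg is None:
                raise ConfigError("with_features=True requires a SpectralConfig")
            seg.features = np.stack([extract_features(p, cfg) for p in patches])
        segments.append(seg)
    return segments
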