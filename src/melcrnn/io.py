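"""Reading, writing, and conditioning continuous multichannel EEG recordings.

Three on-disk forms are supported:

* **EDF** for clinical-style exchange (read through :mod:`mne`; written by a
  minimal built-in EDF+ writer with 16-bit quantisation, intended for
  fixtures and round-trips rather than archival use);
* an **npz container** (named arrays ``data``, ``rate``, ``channel_names``,
  optional ``reference_name``) as the native fixture format;
* **delimited text** (comment header with rate and channel names, one
  channel per row) for tiny hand-made inputs.

Amplitudes are microvolts everywhere in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .errors import ValidationError

__all__ = [
    "Recording",
    "load_recording",
    "save_recording",
    "select_channels",
    "resample",
]


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG: (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...]
    reference_name: str | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise ValidationError(f"data must be 2-D (channels x samples), got shape {data.shape}")
        if data.shape[1] < 1:
            raise ValidationError("recording must contain at least one sample")
        if self.rate <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        if len(self.channel_names) != data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted({n for n in self.channel_names if self.channel_names.count(n) > 1})
            raise ValidationError(f"duplicate channel names: {dupes}")
        bad = ~np.isfinite(data)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite sample at channel {self.channel_names[ch]!r}, index {idx}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".npz":
        return "npz_container"
    return "delimited"


def load_recording(path, format: str | None = None) -> Recording:
    """Load a recording; the format is inferred from the suffix when omitted."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    fmt = format or _detect_format(path)
    if fmt == "edf":
        return _load_edf(path)
    if fmt == "npz_container":
        return _load_npz(path)
    if fmt == "delimited":
        return _load_delimited(path)
    raise ValueError(f"unknown format {fmt!r}; choose edf, npz_container, or delimited")


def save_recording(rec: Recording, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "edf":
        _save_edf(rec, path)
    elif fmt == "npz_container":
        np.savez(
            path,
            data=rec.data,
            rate=np.asarray(rec.rate),
            channel_names=np.asarray(rec.channel_names),
            reference_name=np.asarray(rec.reference_name or ""),
        )
    elif fmt == "delimited":
        header = f"# rate: {rec.rate!r}\n# channels: {','.join(rec.channel_names)}\n"
        if rec.reference_name:
            header += f"# reference: {rec.reference_name}\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, rec.data, delimiter="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _load_npz(path: Path) -> Recording:
    with np.load(path, allow_pickle=False) as npz:
        if "rate" not in npz:
            raise ValueError(f"{path}: container is missing the 'rate' array")
        ref = str(npz["reference_name"]) if "reference_name" in npz else ""
        return Recording(
            data=np.asarray(npz["data"], dtype=float),
            rate=float(npz["rate"]),
            channel_names=tuple(str(n) for n in npz["channel_names"]),
            reference_name=ref or None,
        )


def _load_delimited(path: Path) -> Recording:
    rate = None
    names: tuple[str, ...] | None = None
    reference = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line.lstrip("# ").partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "rate":
            rate = float(value)
        elif key == "channels":
            names = tuple(n.strip() for n in value.split(","))
        elif key == "reference":
            reference = value
    if rate is None:
        raise ValueError(f"{path}: header does not declare a sampling rate")
    data = np.atleast_2d(np.loadtxt(lines[body_start:], delimiter="\t"))
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(data=data, rate=rate, channel_names=names, reference_name=reference)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _load_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    return Recording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
    )


def _save_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF+ writer: one data record per second, 16-bit samples.

    Requires an integer sampling rate.  Physical min/max are taken per
    channel from the data (symmetric), so the quantisation step is
    (2*|x|_max)/65535.
    """
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError(f"EDF export needs an integer sampling rate, got {rec.rate}")
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / rate))
    padded = np.zeros((n_ch, n_records * rate))
    padded[:, : rec.n_samples] = rec.data
    # round the physical range UP to what the 8-char header field can hold, and
    # quantise against the stored value so writer and reader use the same scale
    phys_max = np.array([float(f"{np.ceil(m * 100) / 100:.6g}"[:8])
                         for m in np.maximum(np.abs(padded).max(axis=1), 1.0)])
    dig_min, dig_max = -32768, 32767

    def f(text, width):
        return f"{text:<{width}.{width}}".encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate 01-JAN-2000 X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n_ch)), 8),
            f("EDF+C", 44),
            f(str(n_records), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(f(name, 16) for name in rec.channel_names),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{-m:.6g}", 8) for m in phys_max),
        b"".join(f(f"{m:.6g}", 8) for m in phys_max),
        b"".join(f(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(f(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(str(rate), 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ]
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.clip(np.round(padded * scale[:, None]), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(block)
        for r in range(n_records):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------


def select_channels(rec: Recording, keep: list[str]) -> Recording:
    """Restrict to the named channels, in the order given in ``keep``.

    Dropping the declared reference (e.g. CPZ in an 18-channel montage)
    is done by simply omitting it from ``keep``.
    """
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [name for name in keep if name not in index]
    if missing:
        raise KeyError(
            f"unknown channel(s) {missing}; available: {list(rec.channel_names)}"
        )
    rows = [index[name] for name in keep]
    return replace(rec, data=rec.data[rows], channel_names=tuple(keep))


def resample(rec: Recording, target_rate: float) -> Recording:
    """Polyphase resampling to ``target_rate`` (anti-aliased on the way down).

    The output length is floor(n_samples * target_rate / rate).
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(rec.data, up, down, axis=1)
    n_out = (rec.n_samples * up) // down
    return replace(rec, data=out[:, :n_out], rate=float(target_rate))
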