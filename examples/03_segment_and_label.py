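"""Segment a recording into labeled windows using its PERCLOS trace.

Windows of 1,600 samples (4 s at the 400 Hz working rate) are labeled by
the mean PERCLOS over the window: < 0.35 vigilant, >= 0.35 fatigue (a
three-class scheme adds drowsy at 0.7).
"""

from collections import Counter

from melcrnn import (LabelScheme, SyntheticSpec, build_dataset, generate_recording,
                     resample)

spec = SyntheticSpec(
    state_sequence=(("vigilant", 32.0), ("fatigue", 32.0), ("drowsy", 32.0)),
    seed=7,
)
rec, trace, _ = generate_recording(spec)
rec = resample(rec, 400.0)  # 1,000 Hz acquisition -> 400 Hz working rate
print(f"resampled to {rec.rate:.0f} Hz: {rec.n_samples} samples")

for mode in ("two_class", "three_class"):
    scheme = LabelScheme(mode=mode)
    segments = build_dataset(rec, trace, scheme, window_len=1600, patch_len=200)
    counts = Counter(scheme.class_names[s.label] for s in segments)
    print(f"{mode}: {len(segments)} segments of {segments[0].patches.shape} "
          f"(patches x channels x samples) -> {dict(counts)}")
# Each 4 s window becomes a sequence of eight 200-sample patches — the
# input unit the recurrent classifier consumes.
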