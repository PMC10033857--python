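# Methods

`melcrnn` classifies driver vigilance from multichannel EEG with a log-Mel
spectrogram front end and a convolutional recurrent network (CRNN), using
PERCLOS — the fraction of time the eyelids cover the pupil — as the
behavioural ground truth. This note records the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not establish.

## Signal model and labeling

A recording is a real matrix (channels × samples, µV) with a sampling rate
and channel names. The reference electrode (CPZ in the 18-channel montage
the pipeline is designed around) carries no signal of its own and is dropped
by channel selection, leaving 17 working channels. Recordings are resampled
to a 400 Hz working rate by polyphase filtering (anti-aliased on the way
down); *all* window and patch sizes elsewhere in the package are counted in
samples at this working rate. Both conventions are configurable because the
choice of the rate at which a "1,600-sample window" is counted is genuinely
open; the package fixes "at the working rate" (so one window is 4 s at
400 Hz) and exposes the rate in the config.

PERCLOS over an interval is

    PERCLOS = (blink + CLOS) / (blink + fixation + saccade + CLOS),

with all four durations ≥ 0. Labels: PERCLOS < 0.35 → vigilant, otherwise
fatigue; a three-class scheme adds drowsy at PERCLOS ≥ 0.7. A value exactly
on a threshold maps to the sleepier class — an arbitrary but total tie rule.
A window's PERCLOS is the mean of the trace samples whose timestamps fall in
the window's half-open time span (nearest sample if none do); trace-to-window
alignment finer than this is not modelled.

Segmentation tiles the recording with 1,600-sample windows (stride =
window length by default, i.e. non-overlapping; the stride is a parameter
because overlap is a legitimate augmentation), and each window is split into
eight contiguous 200-sample patches. The 8-patch sequence is the unit the
recurrent model consumes.

## Spectral front end

The STFT is expressed as a strided 1-D convolution. The kernels are the
first N/2 + 1 rows of the N-point DFT matrix times the analysis window:

    real[k, n] =  cos(2πkn/N) · w[n]
    imag[k, n] = −sin(2πkn/N) · w[n],   k = 0 … N/2,

so convolving a patch with both stacks at hop S gives the real/imaginary
STFT parts with no padding or frame centering (frames lie fully inside the
patch). Squaring and summing gives the power spectrogram. The windowed-DFT
formulation has one substantive consequence: the kernels are ordinary
convolution weights and can be *fine-tuned* during training
(`trainable_kernels`, on by default; a frozen mode exists and is what the
oracle tests pin down). Whether fine-tuning helps is an empirical question
the package leaves to the user; both modes run.

Defaults follow the tuned operating point: N = 50 samples, hop 1,
periodic Hann window (w[k] = (1 − cos 2πk/N)/2, which sums to N/2; the
periodic form is the STFT-standard reading of the raised cosine), 400 Hz
rate. Window length equals the kernel size.

The Mel stage places n_mels + 2 points uniformly on the Mel scale
(Mel(f) = 2595·log10(1 + f/700)) between f_min = 0 and f_max = rate/2
(both configurable; the range is an assumption, not a given), maps them
back to Hz and then to the *nearest* STFT bin. Rounded centers that collide
are pushed one bin right so the triangle corners stay strictly increasing —
with 12 filters over 26 bins collisions are possible and the triangles need
distinct corners. Filter m rises linearly to exactly 1 at its center bin and
falls to 0 at its neighbours' centers; filters are **not** area-normalised
(the unnormalised triangle is the definition used). Finally

    LogMel = 10·log10(max(M·P, amin)) − 10·log10(ref)

with amin = 1e-10 guarding log(0) (so a silent patch sits at −100 dB for
ref = 1) and ref = 1 by default; a per-patch `ref="max"` mode exists but is
off because an absolute reference keeps dB values comparable across patches.

## The CRNN

Per patch, the (channels × mel × frames) image passes through three
VGG-style blocks — two 3×3 convolutions (stride 1, padding 1), each followed
by batch normalisation and ReLU, then 2×2 average pooling — with dropout
p = 0.2 after each block. The EEG channels enter as the convolution's input
channels. The block listing is conv–BN–conv–BN–pool with ReLU after each
BN: a "VGG-like" stack without activations would collapse to a linear map,
so the standard VGG placement is used. Global average pooling over the
remaining mel × frame positions yields one feature vector per patch
(width = last conv width). Channel widths default to 64/128/256.

The eight patch vectors feed a two-layer bidirectional recurrent network,
vanilla Elman tanh cells with 128 hidden units per direction (GRU/LSTM are
drop-in alternatives behind a config switch; the plain recurrence is the
default because that is the model's stated form). The classifier consumes
the concatenation of the two directions' *terminal* states — forward state
after the last patch, backward state after the first — each having seen the
whole sequence; pooling over time is deliberately not used because the
classifier is defined on a single feature vector. Then FC(128) → ReLU →
FC(z) → softmax, z ∈ {2, 3}. Dropout is not applied inside the classifier.

Ablation switches reproduce the reduced variants: `frontend="none"` (raw
waveform patches straight to the CNN, entering as height-1 images; pooling
adapts by halving only axes of size ≥ 2), `frontend="power"` (dB power
spectrogram, no Mel projection), `use_rnn=False` (classifier on the mean of
the eight CNN vectors). The attention variant is intentionally absent.

## Training and evaluation

Cross-entropy with natural log (the log base is a convention; metrics are
unaffected, loss magnitudes scale), Adam with learning rate 1e-4,
β = (0.9, 0.999), ε = 1e-8, batch size 64, Xavier-normal initialisation
(variance 2/(fan_in + fan_out), zero biases; the DFT kernels are initialised
to the DFT basis, not Xavier — that initialisation *is* their definition).
The dataset is shuffled and split 8:2; grouped splitting (whole subjects on
one side) is available via a group key for multi-subject data, and a
stratified variant keeps class proportions on both sides of small balanced
datasets. The final-epoch parameters are kept by default; keeping the
best-eval-accuracy epoch is an explicit opt-in, since model selection on the
test split inflates scores.

Metrics come from the confusion matrix of argmax predictions (ties to the
lowest class index): accuracy, precision, recall, F1. Binary runs treat the
fatigue class as positive; three-class runs macro-average. Non-finite loss
aborts with epoch/batch/lr diagnostics instead of continuing silently.

The sweep harness retrains per value of one named parameter (n_fft, hop,
n_mels, rate, patch_len) and emits a four-metric row per value with the
best-accuracy row flagged; invalid grid points become failed rows, not
crashes, so a sweep survives a bad corner of the grid.

## Synthetic data: what it emulates and what it does not

The generator produces per-channel sums of band sinusoids (delta 1–4,
theta 4–8, alpha 8–13, beta 13–30 Hz; frequency drawn uniformly in-band per
channel, random phase) whose amplitudes follow a piecewise-constant state
sequence, plus 1/f background noise (FFT-shaped, unit variance, scale 3 µV)
and white noise (1 µV). Alert state: beta 6 µV, alpha/theta/delta 2 µV;
fatigued: alpha 6, theta 5, beta 2; drowsy: alpha 8, theta 6, beta 1 — i.e.
alert beta is 3× the fatigued level and fatigued alpha 3× the alert level,
mirroring the alpha-rise/beta-drop signature of fatigue EEG. PERCLOS is
sampled at 1 Hz around per-state means (vigilant 0.15 ± 0.05, fatigue
0.50 ± 0.08, drowsy 0.85 ± 0.05, clipped to [0, 1]).

This emulates exactly the feature the pipeline exploits — class-dependent
band power — and nothing else: no volume conduction or inter-channel
correlation, no eye-blink/EMG artifacts, no non-stationarity within a
state, no gradual state transitions. Passing the learning checks therefore
shows the pipeline is *correctly wired and trainable end-to-end*; it says
nothing about accuracy on real driving EEG, where class overlap is the
entire difficulty.

The `easy_preset` builds alternating 8-window state blocks (so windows never
straddle a state change) with at least 64 windows per class, generated at
1,000 Hz and resampled to 400 Hz.

## Desk-scale protocol and problem sizes

The full reference protocol (widths 64/128/256, batch 64, 50 epochs) is the
shipped default configuration. Experiments that run as part of the test
suite and `scripts/acceptance.py` use a desk-scale protocol
(`desk_scale_configs()`): the same architecture with conv widths 16/32/64,
batch 16, six epochs, stratified 8:2 split, standard learning rate. On the
strongly separable preset the model converges within three epochs, so six
epochs carry margin while a complete generate→train→evaluate study stays in
the low minutes on a single CPU core. The three-class study in the
acceptance script uses 32 windows per class and twelve epochs: the finer
fatigue/drowsy distinction converges a few epochs later than the binary
task, and evaluation-mode accuracy additionally waits on the batch-norm
running statistics (momentum 0.1) catching up with the batch statistics. The
shuffled-label control permutes labels over the whole dataset before
splitting; its test accuracy estimates the chance level 1/z.

## Numerical and engineering choices

* Double precision for I/O and feature extraction; the network runs in
  float32.
* The network stack is a small reverse-mode autodiff engine on numpy
  (`melcrnn.nn`): every backward rule is verified against central finite
  differences in the test suite, and convolution additionally against an
  explicit padded correlation. Conv feature maps flow channels-last with a
  chunked im2col + GEMM (column chunks capped near 80 MB) — profiling showed
  this keeps single-threaded BLAS at full speed where naive layouts do not.
* Batch-norm uses batch statistics in training and running statistics
  (momentum 0.1) in evaluation, which makes evaluation deterministic and
  batch-size invariant.
* Average pooling floors odd spatial sizes (trailing row/column cropped) and
  skips axes of size 1.
* EDF export quantises to 16 bits against a per-channel physical range
  rounded up to the header's 8-character precision, so a write-read
  round-trip errs by at most one quantisation step. Reading goes through
  `mne`; the built-in writer exists for fixtures and round-trip tests, not
  archival exchange.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; one seed fans out deterministically to
  generation, splitting, initialisation and dropout. Determinism holds on a
  fixed device (BLAS summation order differs across machines).

## Known limitations

* No artifact rejection, re-referencing beyond dropping the declared
  reference, or band-pass cleaning — raw(ish) signals are a design premise.
* No inverse transform/phase use; the front end is analysis-only.
* The recurrent sequence length is short (8); the BiRNN is not exercised on
  long-horizon dependencies.
* Desk-scale results quantify correctness, not real-data performance; no
  claim is made about accuracy on clinical or driving-study EEG.
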