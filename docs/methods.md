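# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `depspeech`, in the spirit of a package methods
appendix. It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Problem setting

Given a mono recording of one speaker and that speaker's PHQ-8
questionnaire total, the task is binary classification: depressed
(total ≥ 10) versus not. The pipeline is a composition *f(g(signal))* →
label, where *g* maps audio to frame-level features and *f* is a learned
classifier. Labels live at the speaker level; every 1.5 s segment of a
speaker's speech inherits that label, and evaluation is reported both
per segment (default) and per speaker by majority vote over their
segments (ties break to the non-depressed class).

## Preprocessing

* **Voice-activity detection.** Short-time energy gate with 20 ms window
  and 20 ms step. A frame is kept when its mean-square energy is at
  least `energy_threshold_ratio` (default 0.1) times the *median* frame
  energy of the utterance, with an absolute floor of 1e-12 so digital
  silence never passes. Making the threshold relative to the median
  gives scale invariance; the gate is idempotent whenever speech and
  silence energies are clearly bimodal, which is the regime it is meant
  for. The exact VAD algorithm used on the original corpus is a toolkit
  internal; this self-contained energy gate satisfies the same contract
  (silent stretches removed, 20 ms resolution).
* **Segmentation.** After (optionally) removing silence, the signal is
  cut into consecutive non-overlapping windows of 1.5 s; the trailing
  remainder is discarded rather than padded, so every training sample is
  exactly 1.5 s. Both preprocessing variants are supported: with the
  silence gate (the "mute-removed" condition) and without
  (`keep_silence=True`, the "original" condition).

## Features

* **Filterbank.** 25 ms Hamming-windowed frames every 10 ms
  (pre-emphasis 0.97), 512-point FFT power spectrum, 40 triangular mel
  filters spanning 0–8 kHz, log with a 1e-10 floor. Frame count is
  `floor((len − frame_len)/step) + 1`; no end padding.
* **Dynamics.** The delta operator over a ±N window (N = 2 by default)
  with edge replication. Two sign conventions are implemented: the
  standard regression difference (zero on constant input), used by
  default, and a `printed_sum` variant that replaces the inner minus
  with a plus — some sources typeset the formula that way, which makes
  it a smoother with gain (Σn)/(Σn²) on constants (0.6 at N = 2). The
  variant is kept purely for fidelity experiments.
* **3D stack.** static, Δ, ΔΔ on a third axis → frames × 40 × 3.
  **MFCC-39**: DCT-II (orthonormal) of the log-mel energies, first 13
  coefficients, plus Δ and ΔΔ → 39 columns.
* **Fixed-length batching.** The padding length L is the *mode* of the
  utterance frame counts (ties to the smaller value); the source
  material mentions both a mode and an average, and the mode is the
  implemented reading (recorded in the feature sidecar). Items longer
  than L are split into consecutive chunks of L; short chunks are
  zero-padded with a boolean mask of real frames; chunks with fewer than
  10 % of L real frames are discarded. With 1.5 s segments at the
  default frame settings every segment is exactly 148 frames, so L = 148
  and no padding actually occurs in the standard pipeline.

## Architectures

Both models run on a small in-package reverse-mode autodiff engine over
numpy (dense, same-padded 1D/2D convolution via im2col or per-offset
matmuls, batch norm, max pooling, GRU, dropout, Adam, fused softmax
cross-entropy). Gradients are verified against central finite
differences in the test suite.

* **1D baseline** (MFCC input, B × L × 39): four parallel same-padded
  1D convolution branches with kernel sizes 1, 2, 3, 4 (32 filters
  each), concatenated → batch norm → ReLU → max pooling (size 2) →
  single 1D convolution → bidirectional GRU (64 units per direction) →
  flatten → dense softmax.
* **3D model** (B × L × 40 × 3): the same multi-branch idea with k × k
  2D kernels over the time–mel plane (same-size output per branch) →
  ReLU → max pooling → one or more highway layers applied along the
  channel axis, `out = H(x)⊙T(x) + x⊙(1−T(x))` with H = ReLU∘affine and
  T = sigmoid∘affine (the carry gate is tied to 1−T; the gate bias is
  initialised at −1 so training starts near the identity path) → a
  second 2D convolution → ReLU → the mel × channel axes are flattened
  per time step → bidirectional GRU → attention pooling
  (α_t = softmax(W·p_t), stably computed by max-subtraction; padded
  steps are masked with a −1e9 logit bias; the last α per sample is
  exposed for inspection) → dropout → dense softmax.

Layer widths that published figure images leave illegible — filter
counts, pooling size, GRU width, the second convolution — are explicit
`ModelConfig` fields (defaults: 32 filters/branch, pool 2, 64 GRU units,
dropout 0.2, one highway layer) rather than hard-coded constants. Max
pooling is attached to the end of the first convolution stage in both
architectures; since disjoint-window max pooling commutes with ReLU and
with the channel concatenation, it is applied per branch to keep the
large same-size convolution activations short-lived.

## Training

Adam on softmax cross-entropy, batch 60. The reference recipe is
learning rate 1e-5 for 5000 epochs; desk-scale runs use 200 epochs at
1e-3 (the config defaults keep the reference values; the experiment
helpers override both together). Optional inverse-frequency class
weights address label imbalance in the loss; optional early stopping on
validation accuracy (patience 50) exists but is off by default, matching
the fixed-epoch reference recipe. Batch-norm statistics are frozen and
dropout disabled at inference, so single-sample prediction equals the
corresponding row of a batched prediction. All randomness (init,
shuffling, dropout, data synthesis) flows through explicit
`numpy.random.Generator` seeds; two runs with the same seed produce
identical loss histories. A learning rate of exactly 0 is accepted as a
degenerate optimizer (constant loss history), which is useful as a test
contract. Non-finite loss aborts with a diagnostic rather than training
on.

## Metrics

`acc`, `pre`, `error`, F1 with class 1 = depression. Percentages are
rounded half-up to two decimals (Python's bankers' rounding is not
used), F1 to three. `error` is reported as `100 − pre` *after* rounding
so the complementarity `pre + error == 100.00` is exact; direct rounding
of FP/(TP+FP)×100 agrees everywhere except exact half-cent boundaries,
where complementarity is taken to be the stronger contract. Undefined
metrics (no positive calls) raise in the strict functions; the
report-level constructor degrades to NaN with a footnote.

The two confusion fixtures used as worked examples, (tp 7, fp 5, fn 4,
tn 19) and (tp 7, fp 4, fn 4, tn 20), are the unique small-integer
confusions over 35 test interviewees that reproduce all four printed
metric values of the corresponding published result rows
simultaneously; they are exercises for the metric formulas, not claims
about the original experiment. They imply 11 depressed test
interviewees where the published sample table lists 12 — that
discrepancy is in the source material and is surfaced as a report
footnote, not resolved.

## Synthetic corpus

Each utterance is a sequence of voiced "syllables" separated by silent
gaps: per syllable, a fundamental drawn from Normal(f0_mean, f0_sd)
(floored at 30 Hz) with two harmonics at −6 and −12 dB, random phases,
a flat envelope with 10 ms raised-cosine attack/release ramps, and
amplitude jittered by `amplitude_sd`; gap lengths are a Dirichlet split
of the pause budget so the silent share matches `pause_fraction` up to
rounding. White noise is added at `noise_snr_db` (default 30 dB) and the
waveform is rescaled if its peak exceeds full scale. The ramps (rather
than a full-length cosine bell) keep every voiced frame above the energy
gate, so a zero-pause utterance passes the VAD nearly unchanged.

Default class profiles encode the direction of the clinical cues —
control: f0 140 ± 20 Hz, 3.5 syllables/s, 15 % pauses, amplitude 0.6 ±
15 %; depressed: f0 110 ± 8 Hz, 2.0 syllables/s, 35 % pauses, amplitude
0.3 ± 5 %. The magnitudes are package choices, deliberately
well-separated. The default corpus is 20 utterances per class of 3.0 s
each at 16 kHz; after silence removal each utterance yields one 1.5 s
segment, giving a 40-segment corpus that trains in minutes on one CPU
core.

What the generator does **not** emulate: phonetic content, formant
structure, co-articulation, speaker identity beyond the class profile,
channel/room effects, interviewer speech, or any overlap between the
class distributions. Passing the end-to-end test therefore shows that
the pipeline can learn well-separated spectro-temporal class structure
from raw audio through the full stack — it says nothing about
performance on real clinical speech.

## Desk-scale experiment configuration

The end-to-end experiment (`depspeech.experiments`) keeps the published
layer structure at reduced cost: 32 filters per branch, 64 GRU units,
one highway layer, 200 epochs, three seeds — with pooling 6,
16 second-stage filters, learning rate 1e-3 and inverse-frequency class
weights (the depressed profile's larger pause share yields fewer
segments per utterance, so the segment classes are imbalanced by
construction). Speakers are split 70/30 into train/test,
stratified by class, so held-out accuracy is measured on speakers never
seen in training. The matched null control regenerates the corpus with
both classes sharing the control profile; with no class signal the
trained model's held-out accuracy should sit near chance, and the test
suite asserts 50 % ± 10 % averaged over three seeds.

## Known limitations

* The synthetic classes are far easier to separate than real depressed
  versus control speech; absolute accuracies here do not transfer.
* The numpy engine is single-device and unoptimised beyond BLAS-sized
  matmuls; the reference 5000-epoch recipe is impractical on it.
* The 1D baseline's flatten head ties its parameter count to the padded
  length L; models must be rebuilt for a different L.
* No speaker diarization: recordings are assumed to contain one speaker.
* PHQ-8 binary labeling only; severity grading and other instruments are
  out of scope.
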