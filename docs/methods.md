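# Methods

This note records the model conventions, parameter choices and numerical
decisions behind `bsound`, and what the synthetic-data experiments do and do
not demonstrate.

## Signal model and spectrogram conventions

The pipeline treats an abdominal recording as sparse short bursts (bowel
sounds, ~20–130 ms, energy in 60–1500 Hz) embedded in broadband background
noise. All analysis runs at 44,100 Hz mono; arbitrary PCM/float WAV input is
mean-downmixed and resampled on ingest. Recordings are cut into 2-s
fragments; a trailing remainder shorter than one fragment is discarded
rather than padded, so no fabricated silence enters training labeled as
noise. Fragments are processed independently; a sound spanning a boundary
arrives as two touching events (an optional post-hoc merge,
`events.merge_adjacent`, is provided but off by default).

The STFT is the literal windowed DFT: column m covers samples
[m·hop, m·hop + L), there is no centering and no zero-padding, and the
column count is floor((n−L)/hop) + 1. Defaults: L = 441 (10 ms), hop =
floor(L/4) = 110, Hann window. When L is swept, the hop follows floor(L/4).
Window functions use the symmetric convention with denominator N = L − 1,
so the Hann endpoints are exactly zero.

Spectrograms are amplitude decibels, 20·log10(|X|) with reference 1.0,
clamped at a floor of −100 dB (the floor only matters for exact zeros, e.g.
digital silence). A linear frequency axis is kept deliberately: the band of
interest is narrow and low, so a Mel warp would add nothing. The 0–1500 Hz
"low-pass" is realized purely as a crop of DFT bins: bins with
0 < f ≤ max_freq are retained. DC is excluded because it carries sensor
offset rather than sound, and because at the defaults (bin spacing
44,100/441 = 100 Hz) exclusion yields exactly 15 bins — the input height
the frame classifiers are sized for.

Standardization is global and scalar: one mean and one standard deviation
of dB values over all training spectrograms, stored with a trained model
and reapplied verbatim at detection time. When the baseline detector is run
without a model, the incoming recording's own global statistics are used.

### Frames

A frame is 10 ms = 441 samples, the atomic classification unit. Frame m is
paired with the 4 consecutive spectrogram columns starting at
c_m = floor(m·441/110); because 441 = 4·110 + 1, this start index drifts by
one column every ~110 frames, which the floor absorbs. Frames at the
fragment end whose column window runs past the spectrogram are zero-padded
on the right, so every frame block is exactly 15×4 and regrouping never
alters a value. A 2-s fragment yields exactly 200 frames.

### Labeling rule

A frame is a bowel-sound frame when (a) annotated sound covers strictly
more than half the frame, or (b) strictly more than half of one annotated
sound's duration lies inside the frame. Rule (b) exists for sounds shorter
than a frame. Frames are half-open intervals [m·Δ, (m+1)·Δ), so a boundary
instant never counts twice; an overlap of exactly Δ/2 is negative. The
implementation is checked against an exhaustive per-frame overlap oracle on
randomized instances.

## Classifiers

All classifiers consume standardized 200×15×4 fragment tensors and emit one
probability per frame; decisions use a 0.5 threshold (configurable — the
probability scale is calibrated only implicitly through the loss).

**Baseline.** Frame score = mean of its 15×4 standardized block (the
0–1500 Hz band); decision = score > cutoff. Decisions are monotone in the
cutoff by construction. The cutoff (default 0.07, in standardized-dB units)
is the detector's only parameter and is exposed in the configuration.

**CRNN** (342,281 parameters). Per frame: Conv 30@3×3 → Conv 60@4×2, valid
padding, stride 1, ReLU (15×4 → 13×2 → 10×1), flattened to 600 features;
dropout 0.4; a bidirectional GRU with 80 units per direction over the
200-frame sequence; dropout 0.4; per-frame dense(1, sigmoid). The GRU uses
the reset-after ("double bias") gate formulation — separate input and
recurrent biases per gate, with the reset gate multiplying the biased
recurrent candidate term — which is what makes the parameter count come out
at 2·3·(600·80 + 80·80 + 2·80) = 327,360 for the recurrent layer. The
candidate activation is ReLU (gates are sigmoids). No pooling layers: the
printed tensor shapes only reconcile without them.

**CDNN** (115,521 parameters). Per frame: flatten (60) → dense 120, ReLU;
then the feature vectors of the 9 adjacent frames (±4) are concatenated
(zero vectors beyond the sequence edges, so every frame stays classifiable)
→ dropout 0.4 → dense 100, ReLU → dense 1, sigmoid. Context width 9 trades
a small accuracy loss for far fewer parameters than wider windows.

**Training.** Per-frame binary cross-entropy (computed on logits for
stability), Adam with the conventional defaults (lr 1e-3, β₁ 0.9, β₂ 0.999),
minibatches of 16 fragments, inverted dropout. Per-epoch validation
accuracy/precision/sensitivity/specificity are recorded and the retained
checkpoint is the best epoch by validation accuracy. No class weighting is
applied despite the class imbalance; imbalance is handled by reporting
sensitivity and specificity separately. Optional augmentation adds i.i.d.
Gaussian noise (σ configurable, 5 copies per sequence by default, originals
retained) to the standardized spectrogram values.

The layers run on a small in-package reverse-mode autodiff over NumPy
(`bsound.nn`), with convolutions expressed as shifted matrix products and
the bidirectional GRU as a single fused graph node with hand-derived
backpropagation through time. Analytic gradients are verified against
central finite differences in the test suite. Everything is float64 and
deterministic given the seed: identical seeds reproduce identical training
histories bit for bit.

## Events and statistics

Maximal runs of consecutive positive frames become events (start/end on the
10-ms frame grid, mean probability over the run). No minimum duration and
no gap bridging by default; both are available as options but change the
reported counts, so they are off in the reference pipeline.

Inter-event intervals are onset-to-onset — the heart-rate-variability
convention the named statistics come from. On the interval sequence I with
differences Δᵢ = Iᵢ₊₁ − Iᵢ:

* SD of intervals: sample standard deviation (ddof = 1);
* RMSSD = sqrt(mean(Δᵢ²));
* Porta's index = 100 · #{Δᵢ < 0} / #{Δᵢ ≠ 0};
* Guzik's index = 100 · Σ_{Δᵢ>0} Δᵢ² / Σ_{Δᵢ≠0} Δᵢ² (the 1/√2
  Poincaré-distance factor cancels).

Statistics with an empty domain (fewer than two intervals; no nonzero Δ)
are reported as `None`, never as 0, so degenerate recordings cannot
masquerade as symmetric ones.

The report's per-minute series covers the whole minutes floor(T/60)
(events binned by onset); three-minute windows are consecutive
non-overlapping groups of whole minutes summarized by mean/median/Q1/Q3 of
their per-minute counts ("quartiles" is our reading of the looser term
sometimes used for this summary). The duration histogram bin b covers
((b−1)·10, b·10] ms, partitioning the duration axis; percentages are shares
of n_events. The overall `events_per_min` is computed over whole minutes
(full duration only for recordings shorter than one minute): this makes
every statistic except the raw recording length invariant to an event-free
trailing partial minute, at the cost of ignoring events' absence in the
tail. Incomplete trailing minutes are excluded from the per-minute series
but their events still count in totals and interval statistics.

## Synthetic data: what it emulates and what it does not

The generator produces Gaussian background noise (RMS 0.01) with
exponentially damped sinusoid bursts: carrier uniform in 60–1500 Hz,
duration uniform in 20–130 ms, onsets from a Poisson process thinned by
rejection so bursts never overlap or run past the end, amplitude set so the
burst's in-band RMS exceeds the noise RMS by the configured SNR (default
15 dB — bowel sounds are mostly quiet against the background, and lower
SNRs keep the detection task nontrivial). Annotations are the exact burst
supports, so ground truth is perfect by construction.

Two consequences of the rejection thinning are worth knowing: the realized
event rate sits slightly below the configured rate (by roughly the busy
fraction, e.g. ~2–3% at 20 events/min of 75-ms bursts), and dense settings
(rate × mean duration > 80% of the recording) are refused outright.

Damped sinusoids were chosen over filtered-noise bursts because they match
the "single burst" phenomenology of short bowel sounds and have analytically
known band content, which the in-band-energy tests rely on. What the
synthetic data does **not** emulate: heartbeat/respiration artifacts, sensor
contact noise, the heavy-tailed amplitude distribution and within-burst
spectral structure of real bowel sounds, multi-burst and harmonic sound
types, and annotation uncertainty (real labels have fuzzy onsets/offsets).
Passing the synthetic-recovery tests therefore demonstrates that the
pipeline is implemented correctly and can learn the mapping it is meant to
learn — not that it attains any particular accuracy on clinical recordings.

## Experiment scales and determinism

Desk-scale experiment sizes were chosen so the whole suite runs comfortably
on one CPU: parameter-recovery training uses a 240-s synthetic recording
(40 events/min, SNR 20 dB), a fragment-level 85/15 split, and a CDNN
trained 12 epochs, repeated over 3 seeds with the median reported (about
20 s per run). Under those conditions held-out frame accuracy lands around
99.5% with specificity ~99.8% and sensitivity well above 90% — far above
the all-negative baseline (~95–96% accuracy at the ~4–5% positive-frame
fraction these settings produce). Cross-validation and sweep helpers expose
the same protocol at configurable scale; running the full fivefold protocol
with 100-epoch budgets on the openly deposited clinical dataset is an
external benchmark outside the test suite.

Splits operate on whole 2-s fragments, never inside one, so near-identical
neighbouring frames cannot leak between train and test. All randomness —
generator, initialization, shuffling, dropout, splits — flows from explicit
seeds through `numpy.random.Generator`.

## Known limitations

* Detection quality on real recordings is unvalidated within this package
  (see above); the classifier thresholds (0.5) and baseline cutoff (0.07)
  are conventions, not calibrated operating points.
* Fragment independence means sounds spanning a 2-s boundary are split;
  `merge_adjacent` repairs touching events but cannot repair a probability
  dip at the boundary.
* The NumPy training loop is single-threaded-CPU oriented; it is entirely
  adequate at desk scale but not a substitute for a GPU framework at
  hundreds of thousands of training sequences.
* 8-bit WAV input is accepted but quantization noise at that depth is large
  relative to quiet bowel sounds.
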