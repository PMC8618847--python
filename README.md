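# bsound

Detection and quantification of bowel sounds in abdominal audio recordings.

Bowel sounds (BS) are short acoustic bursts — typically 20–130 ms long with
energy concentrated in 60–1500 Hz — produced by gastrointestinal motility.
Counting and characterizing them in long (overnight) recordings gives a
non-invasive window on intestinal motor function, but doing it by hand over
hours of audio is impractical. `bsound` implements a complete pipeline for
clinicians and researchers working with such recordings: it turns a WAV file
into decibel spectrograms, classifies every 10-ms frame as *bowel sound* vs
*noise*, merges adjacent positive frames into discrete sound events, and
summarizes the recording with clinically oriented statistics.

## Method

A recording (mono, 44.1 kHz; other rates are resampled on ingest) is cut
into 2-s fragments and each fragment is transformed with the short-time
Fourier transform

```
X[k, m] = Σ_{n=0}^{L-1} w_n · x[m·hop + n] · e^(−2πikn/L)
```

with a Hann window of L = 441 samples and hop 110 (25%). Amplitudes are
mapped to decibels, the frequency axis is cropped to 0–1500 Hz (15 bins at
100 Hz spacing, DC excluded), values are standardized by the global
mean/variance of the training material, and columns are regrouped into 200
frames of 15×4 values per fragment. A frame is labeled a bowel sound when
annotated sound covers more than half the frame, or when more than half of a
single sound's duration falls inside it.

Three frame classifiers share this input:

* **baseline** — mean standardized amplitude of the frame block against a
  fixed cutoff;
* **CRNN** — per-frame convolutions (30 filters 3×3, then 60 filters 4×2,
  valid padding, ReLU) flattened to 600 features, a bidirectional GRU with
  80 units over the 200-frame sequence, and a per-frame sigmoid unit
  (342,281 trainable parameters);
* **CDNN** — per-frame flatten → dense 120 (ReLU), concatenation of the 9
  adjacent frames' feature vectors, dense 100 (ReLU) → sigmoid (115,521
  parameters).

Networks are trained with per-frame binary cross-entropy and Adam, keeping
the epoch with the best validation accuracy; optional augmentation adds
Gaussian noise to the standardized spectrograms. Consecutive positive frames
are merged into events, and a recording is summarized by event counts and
rates, per-minute series with 3-minute window statistics, a duration
histogram, and interval statistics borrowed from heart-rate-variability
analysis: SD of inter-onset intervals, RMSSD, and the Porta and Guzik
asymmetry indices of the interval Poincaré plot.

A seeded synthetic-recording generator (damped-sinusoid bursts over Gaussian
noise, Poisson onsets, exact ground-truth annotations) makes every stage
testable without clinical data. The neural layers run on a small built-in
NumPy automatic-differentiation engine, so the package has no deep-learning
framework dependency.

## Worked example

Generate a 2-minute synthetic recording, train a CDNN on it, detect, and
analyze:

```
$ bsound synth --duration 120 --rate 40 --snr 20 --seed 7 --out rec.wav --ann truth.csv
wrote 120.0 s with 52 events to rec.wav

$ bsound train --model cdnn --wav rec.wav --ann truth.csv --epochs 10 --seed 7 --out model
best epoch 9: accuracy 99.72%, specificity 99.77%
model saved to model

$ bsound detect rec.wav --model model --out detections.csv --report report.json
52 events written to detections.csv

$ bsound analyze detections.csv --length 120 --out report2.json
recording_length_s: 120.000
n_events: 52
events_per_min: 26.0000
per_minute_counts: [23, 29]
...
rmssd_s: 3.0252
sd_intervals_s: 1.9332
porta_index_pct: 52.0000
guzik_index_pct: 51.4168
```

The model recovers all 52 injected events (held-out frame accuracy 99.7%).
`events_per_min` is the rate over whole minutes; the event rate of 26/min
reflects that the generator rejects bursts that would overlap, so the
realized rate sits below the configured 40/min at this density and seed.
`porta_index_pct`/`guzik_index_pct` near 50 say the interval sequence shows
no acceleration/deceleration asymmetry — as expected for a memoryless
synthetic rhythm.

The same stages are available as library functions (`bsound.spectro`,
`bsound.detectors`, `bsound.events`, `bsound.stats`, ...); see the module
docstrings and `docs/methods.md`.

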