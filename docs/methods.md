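# Methods

## The detector

The detector segments the ECG's energy envelope rather than its raw
waveform. After zero-phase Butterworth band-pass filtering and point-wise
squaring, two uniform moving averages are computed over the squared signal:
one whose window matches the duration of a QRS complex (`W1`) and one
matching a whole heartbeat (`W2`). Wherever the QRS-scale average exceeds
the beat-scale average plus an offset `α = β·z̄` (with `z̄` the mean of the
squared filtered signal over the whole record), the samples form a
candidate block; blocks at least `W1` samples wide are accepted as QRS
complexes and the R peak is the largest `|x[n]|` inside each.

The beat-scale average acts as a *data-driven threshold*: it tracks the
local energy level beat by beat, so no adaptive threshold state or
heart-rate history is needed. The assumptions are those of the knowledge
base behind the windows: QRS complexes last roughly 80–120 ms, a beat
roughly one second, and QRS energy is concentrated in the passband while
P/T waves and baseline wander are not. Rhythms that break the beat-scale
assumption severely (e.g. ventricular flutter, where no isolated QRS
exists) are known failure modes of this scheme.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| `f1`, `f2` | passband of the Butterworth filter | 8, 20 | Hz |
| `w1_ms` | QRS-scale window `W1` | 97 | ms |
| `w2_ms` | beat-scale window `W2` | 611 | ms |
| `beta` | offset fraction `β` of the mean squared signal | 0.08 | — |
| `order` | Butterworth order of the single-pass design | 3 | — |

The defaults are the top-ranked combination of an exhaustive grid search
over the MIT-BIH Arrhythmia Database. Parameters are stored in physical
units and converted to samples per record (`W` samples =
round(ms·fs/1000), half away from zero, floor 1), which reproduces the
canonical conversions at 360 Hz: 97 ms → 35 samples, 611 ms → 220, 1 s →
360, and the QRS normal limits 80/120 ms → 29/43. An `odd` rounding mode
forces odd window lengths for strictly symmetric centered windows; it is
not the default because the optimized beat-scale window (220 samples) is
even. Even windows use the left-heavy span `[n−W/2, n+W/2−1]`; at record
edges the window shrinks to the available samples and divides by the
actual count.

A note on the offset fraction: some descriptions of this optimum quote
"0.8", which is inconsistent with the accompanying table's "8" in a
percent column; this package uses β = 0.08 and treats 0.8 as a
transcription error.

## Numerical choices

- **Zero-phase filtering.** The filter runs forward and backward
  (`sosfiltfilt`), so the effective magnitude response is the squared
  single-pass response and peaks are not displaced in time. One second of
  reflected signal is prepended/appended and trimmed to suppress edge
  transients; tests exclude one second at each edge where approximate
  statements (DC removal, gain) are asserted.
- **Strict vs. inclusive comparisons.** Block membership uses strict
  `MA_qrs > MA_beat + α`; width acceptance uses inclusive `width ≥ W1`.
- **Tie-breaks.** The per-block argmax returns the earliest index on ties.
  The grid-search table breaks overall-accuracy ties by higher SE, then
  lower `W1`, `f1`, `f2`, `W2`, `β`, so the ranking is independent of grid
  enumeration order.
- **Degenerate inputs.** NaN/Inf samples, empty records, non-positive
  sampling rates, bands at/above Nyquist, and records shorter than one
  `W2` window are rejected with descriptive errors rather than patched.
- **Blocks touching the record edges are kept**; callers who distrust the
  first/last beat can trim.
- **Batch semantics.** `z̄` is a whole-record mean; a streaming/windowed
  variant is out of scope.

## Evaluation

Detections are matched to reference beats one-to-one by greedy
nearest-neighbour within ±150 ms (the conventional beat-matching window;
configurable — the tolerance materially affects FP/FN counts and published
benchmarks rarely state theirs). SE = TP/(TP+FN), +P = TP/(TP+FP), overall
accuracy = (SE + +P)/2. Records with no reference beats or no detections
report `None` rather than 0 for the undefined ratios. Corpus-level scores
pool TP/FP/FN across records before forming percentages.

## The optimizer

`brute_force_optimize` enumerates every admissible grid combination
(`f1 < f2`, `W1 < W2`), scores each over the corpus, and returns rows
sorted by descending overall accuracy. The default grid spans passbands
within 1–26 Hz, `W1` ∈ 55.5–111.1 ms (20–40 samples at 360 Hz), `W2` ∈
555.5–694.4 ms (200–250 samples), and β ∈ 0–10 %. Internally combinations
are grouped by frequency band so each record is filtered once per band;
this is a pure reordering of independent computations and leaves every
score bit-identical to the naive loop.

## The Pan–Tompkins comparator

The comparator follows the classic step order: polyphase resampling to
200 Hz, mean subtraction, 5–15 Hz band-pass, five-point derivative,
squaring, 150 ms moving-window integration, then peak classification with
running signal/noise levels (`SPKI`/`NPKI`, threshold
`NPKI + 0.25·(SPKI−NPKI)`), a 200 ms refractory period, and a search-back
pass at half threshold when no beat appears within 166 % of the average of
the last eight RR intervals. The first two seconds initialise the levels.
Detected peaks are localised on the band-passed signal and mapped back to
the original record's sample coordinates, with a ±50 ms refinement at the
original rate. The implementation follows the published adaptive-threshold
rules; it is a floating-point reimplementation, not a bit-exact port of
the original integer code.

## The synthetic generator

Each record is a train of Gaussian pulses per beat — P wave (110 ms wide,
160 ms before the R apex), QRS (100 ms), T wave (160 ms, 300 ms after R) —
with widths interpreted as the ±2σ span and amplitudes 0.15/1.0/0.3 mV.
Scheduled R-apex times are snapped to the sample grid *before* rendering,
so the stored ground truth is exact at any sampling rate. Optional
morphology flags invert, widen (×1.8) or make biphasic the QRS, or drop
the P wave. Noise is added after ground-truth extraction: 60 Hz mains with
second/third harmonics at 50 %/25 % of the fundamental, sub-1 Hz sinusoidal
baseline wander (default 0.33 Hz), white Gaussian "muscle" noise, and
Gaussian RR jitter truncated at ±3σ to preserve beat ordering. Everything
is driven by one `numpy` Generator seed; identical specs produce identical
arrays.

What it does *not* emulate: real QRS micro-structure (notching), rhythm
disorders (flutter, fibrillation), pacing artifacts, electrode pops,
non-stationary noise, or annotation error. Passing the synthetic suite
therefore demonstrates the detector's *contracts* — correct segmentation
arithmetic, scale/DC invariance, graceful degradation under additive
noise — not clinical-grade accuracy; that requires the standard annotated
databases, which the `evaluate`/`compare` harness can score when the
records are supplied (WFDB reading needs the optional `wfdb` package).

## Problem sizes used in the test and acceptance suites

Chosen as desk-scale renderings of the detector's operating range: the
noise-free sweep uses 30 s records at five heart rates (40–180 bpm) ×
five sampling rates (128–1000 Hz); stage-level brute-force oracle checks
run on 1000 random instances of length ≤ 120; optimizer recovery uses a
48-combination grid over five 20 s records; the degradation check uses
five noise levels on 60 s records with a fixed seed.

## Known limitations

- Sample-resolution block boundaries; no sub-sample R-peak interpolation.
- The whole-record mean in the offset makes the detector a batch
  algorithm; very long records with grossly non-stationary noise would be
  better served by chunked processing.
- Wide (e.g. bundle-branch-block-like) QRS complexes lose energy in the
  8–20 Hz passband; sensitivity survives but positive predictivity can
  drop as P/T-wave blocks become comparatively larger.
- The width rule rejects blocks narrower than `W1`, so very fast rhythms
  whose energy blocks merge or shrink can be missed.
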