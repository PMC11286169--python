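# Methods

This note documents the models, conventions and numerical choices
behind `szevents`, in the order the pipeline applies them.

## Data model

A **record** is one continuous EDF recording: 22 bipolar scalp-EEG
channels in a fixed canonical order (FP1-F7 … FT10-T8), 256 Hz, 16-bit,
microvolts. Records that do not carry the full canonical montage are
excluded (and counted) rather than padded — mixing montages would
change feature meaning silently. Raw samples are never filtered,
rescaled or artifact-corrected on ingestion; every downstream transform
works on copies.

A **subject timeline** is the subject's records sorted by their
header clock times (the annotation summaries give wall-clock start/end
times; a start time earlier than its predecessor's is interpreted as a
midnight wrap and advanced by 24 h). Inter-record gaps are collapsed:
event logic treats consecutive records as contiguous, because the
recordings are described and annotated as one continuous monitoring
session. A `break_at_record_boundaries`-style treatment can be
recovered by evaluating records separately; the collapsed convention is
the default everywhere. Hours observed for false-detection rates are
the summed record durations.

Time is in seconds throughout; segment `i` of a timeline covers the
half-open interval `[5i, 5(i+1))` in collapsed time. Annotation
intervals are clipped to the segmented extent of their record (a
trailing sub-window remainder carries no segments) and pieces that
touch across a record boundary are merged.

## Segmentation and labeling

Windows are 5 s, non-overlapping, and a trailing remainder shorter than
the window is dropped — padding would fabricate signal. A window is
ictal (label 1) when its total overlap with annotated seizure time is
at least 60% of the window (3 s), the comparison inclusive; overlap
from multiple annotations is summed before thresholding.

## Feature catalog (92 per channel)

The catalog is registry-driven (a list of `FeatureDef`s, extensible
with custom callables); the default contains four families:

* **Time statistics (18)** — mean, median, SD, variance, skewness,
  kurtosis, RMS, peak-to-peak, min, max, mean absolute deviation, IQR,
  energy, line length, zero crossings about the mean, and the Hjorth
  activity/mobility/complexity triple.
* **Entropy-profile descriptors (12)** — the sample-entropy profile is
  SampEn(m=2, r) evaluated on the tolerance grid `r_j = j·d_max/R`
  (R = 50), where `d_max` is the maximum pairwise Chebyshev distance
  between length-m templates, so the grid always spans the window's
  matching range. All R values come from one cumulative histogram of
  pairwise distances, not per-tolerance recomputation; a numba kernel
  does the pair counting and reproduces the brute-force counts bit for
  bit (arithmetic binning with an exact boundary comparison). The
  profile is summarized by max, mean, median, SD, skewness, kurtosis,
  trapezoidal area over r, range, argmax tolerance as a fraction of
  d_max, the value interpolated at the conventional r = 0.2·SD(x),
  the count of finite points, and the terminal value. SampEn is
  undefined when no template pairs match (B = 0 → NaN) or no extended
  pairs match (A = 0 → +inf); undefined points are excluded from the
  summary statistics.
* **Band statistics (5 × 8)** — on a zero-phase 4th-order Butterworth
  band-limited copy of the window (δ 0.5–4, θ 4–8, α 8–13, β 13–30,
  γ 30–80 Hz): absolute power (mean square), relative power against the
  0.5–80 Hz-filtered total, mean absolute amplitude, SD, skewness,
  kurtosis, line length, and the peak Welch-spectrum amplitude inside
  the band. Filtering is per window (not per record) so every segment's
  features depend only on its own 1280 samples.
* **Spectral descriptors (22)** — from the Welch spectrum of the raw
  window (1-s Hann windows, 50% overlap; 1 Hz resolution), restricted
  to 0.5–80 Hz: total power; normalized Shannon, Rényi (α=2) and
  Tsallis (q=2) spectral entropies; spectral edge frequencies at
  50/75/90/95% cumulative power; peak frequency; spectral centroid,
  spread, skewness, kurtosis, flatness and crest factor; the six band
  ratios δ/θ, θ/α, α/β, β/γ, (δ+θ)/(α+β), (α+β)/(δ+θ+γ); and median
  power.

Per segment, the 22 channels' vectors are concatenated channel-major:
2024 columns named `<channel>/<feature>`.

**NaN policy.** Degenerate inputs (constant windows, empty spectra,
undefined SampEn) produce non-finite feature values; these are replaced
by 0 and logged, keeping chi-squared scoring and tree learners defined.
All 0/0 ratios (relative power of a silent window, metric denominators)
resolve to 0 by convention.

**Known numerical behavior.** On a 5-s window the zero-phase filter
transient at the 0.5 Hz delta edge is long relative to the window, so
white-noise delta relative power exceeds its ideal bandwidth share
(~2× in practice); the other bands track the filter's |H|⁴ integral
closely. The entropy-profile monotonicity (values non-increasing in r)
holds on all signals tested but is not a theorem — A/B is a ratio of
two counts that both grow with r — so the code never enforces it.

**Bulk extraction.** `extract_table` vectorizes every family across all
segments of a channel (one filtfilt/Welch call per channel per record);
only the O(N²) entropy kernel runs per segment. `entropy_stride`
decimates the window (stride 2 → 640 samples) for the entropy family
only; bulk runs use stride 2, single-segment calls default to the full
1280 samples.

## Feature selection

The chi-squared score of a feature is computed on per-class feature
mass: with each feature min-max rescaled to [0, 1] on the scoring
sample, observed class-c mass `O_c = Σ_{y=c} f`, expected mass
`E_c = (Σf)·N_c/N`, score `Σ_c (O_c−E_c)²/E_c`. Scores are normalized
to weights summing to 1; selection is the minimal descending-weight
prefix whose cumulative weight reaches 0.9, ties broken by catalog
order (determinism). Correlation (absolute Pearson), decision-tree
impurity and random-forest permutation importances are available for
method comparison through the same protocol: segments of five random
subjects, scored channel-wise on five random channels, weights averaged
across channels per method.

The classifier uses a fixed per-channel count (default 34 → 748
columns) from the channel-averaged chi-squared ranking, applied
identically to every channel, rather than the cutoff's per-run count —
this keeps the classifier dimension reproducible while the protocol
reports what the cutoff would select. Selection is performed once,
globally, before splitting (matching the experimental design this
package reproduces); per-fold selection would be the leakage-strict
variant and can be run by calling the selector inside a fold loop.
Selection uses the raw (imbalanced) sample.

## Splits, balancing, classifier

Subject-wise 5-fold shuffles subjects and cuts them into five groups
differing in size by at most one; leave-one-out makes one fold per
subject; the random-segment mode (80:20 over rows) exists as the leaky
baseline. Training folds are balanced by undersampling: all ictal rows
kept, an equal-count random subset of interictal rows drawn without
replacement; test folds are never touched.

The segment classifier is a random forest; only `n_estimators` is
tuned, over {15, 21, 30, 50, 75}. The search holds out 30% of the
*training subjects* (at least one, never all), scores each grid value
by validation segment sensitivity — chosen because event sensitivity is
the headline quantity; the objective is configurable to F1 — with ties
going to the smaller forest, then refits the winner on the full
balanced training table. One root seed fans out (via `SeedSequence`)
to the split, each fold's undersampling, validation subject draw and
forest.

## Event generation and scoring

Per-segment predictions, ordered along the collapsed timeline, are
post-processed in two steps whose order matters and follows the
procedure this package reproduces: (1) predicted seizure runs of total
duration ≤ 10 s are deleted (run length judged on the raw sequence);
(2) non-seizure gaps ≤ 10 s *between two surviving runs* are filled.
Both thresholds are inclusive. The output's runs and internal gaps all
exceed 10 s, so the operation is idempotent. The fill-first alternative
is intentionally not the default and is distinguished by tests.

Matching uses pooled coverage: for each true event, all detected
seizure time inside it is summed and the event counts as detected (one
TP, regardless of how many fragments contributed) when coverage reaches
0.70, inclusive. Undetected stretches inside a matched event are
forgiven. A detected event overlapping only *failed* true events is
discarded — neither TP nor FP — the conservative reading of partial
detections; `partial_overlap_as_fp=True` switches to counting them as
false positives. A detected event with zero overlap with every true
event counts exactly one FP. Scores: event sensitivity
`100·TP/(TP+missed)` (reported as 0, with a warning, for seizure-free
timelines) and FDR `FP/hours`. Per-subject scores are averaged (not
pooled) into the overall row, the convention for cross-subject event
reporting.

## Synthetic corpus

The generator emulates the statistics the pipeline is sensitive to,
not physiological EEG (no dipole/forward modelling, no artifacts):

* **Background**: per-channel AR(2) noise with subject-level pole
  radius (0.92–0.985) and resonant frequency drawn once per subject,
  plus small per-channel jitter — inter-subject differences exceed
  intra-subject ones, the property that makes cross-subject evaluation
  hard. The resonance is drawn from 8–12 Hz (posterior-rhythm range),
  deliberately disjoint from the ictal rhythm band so the seizure
  signature is spectrally distinct from every subject's background.
  Background SD defaults to 30 µV with a ±30–40% subject-level factor.
* **Seizures**: rare intervals (defaults: 1–3 per subject, 20–180 s,
  uniform integer-second durations) placed with ≥ 30 s clearance from
  record edges and each other. The signature is a multiplicative
  amplitude gain plus an additive 3–7 Hz sinusoidal burst with 2-s
  linear onset/offset ramps, applied to a random subset of 8–22
  channels (generalized vs focal events). The burst amplitude scales
  with (gain − 1), so gain = 1.0 is *exactly* no effect — the
  effect-size dial used by the null-recovery tests — and gain ≥ 3 a
  clearly separable event.
* **Determinism**: every subject's stream is seeded by
  (root seed, subject index), so subjects are reproducible
  independently and under parallel generation.
* **Scale**: defaults (24 subjects, six 1-h records each) put the
  segment-level class imbalance near 1:100 or rarer, the continuous-
  monitoring regime. Tests and the end-to-end evaluation use smaller
  corpora — e.g. 8 subjects × 2 × 10-min records with 2–3 seizures of
  30–90 s — chosen so the full pipeline (feature extraction dominates)
  completes in minutes on one CPU; at that scale the imbalance is
  milder (~1:9), so the end-to-end checks exercise the machinery and
  effect-size dial rather than the extreme-imbalance operating point.
* **Persistence**: corpora round-trip through real EDF files (16-bit
  quantization, within 1 LSB) and integer-second annotation summaries
  identical to the in-memory truth.

What passing synthetic tests does *not* show: robustness to artifacts,
electrode pops, montage drift, non-stationary backgrounds, or seizure
morphologies that differ from rhythmic amplitude increases; real-data
sensitivity/FDR will be substantially worse than on this generator.

## Limitations

* The 92-entry catalog is this package's reconstruction of the named
  feature families; the registry accepts a replacement list without
  code changes.
* Only `n_estimators` is tuned; the forest otherwise uses library
  defaults.
* Coverage threshold (0.70), run/gap thresholds (10 s) and the
  per-channel selection count (34) are parameters with the defaults
  documented above, not re-derived per run.
* Event scoring follows the strict 70%-coverage convention; standard
  any-overlap OVLP or time-aligned scoring variants are out of scope.
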