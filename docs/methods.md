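# Methods

This note documents the models and procedures implemented in pulseman,
the parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the design was genuinely
open.

## PPG preprocessing and signal quality

The preprocessing chain is: zero-mean unit-variance normalization
(population SD; zero-variance input is an error), Hampel outlier
replacement, zero-phase Butterworth band-pass, derivative-based cycle
detection, and sliding-window template screening.

**Hampel filter.** Outliers are *replaced* by the local median rather
than deleted, preserving the uniform sampling the downstream filters
assume.  The default window is 11 samples (`half_window=5`, the
conventional realization of a "10-sample" neighbourhood); the threshold
is `3 x 1.4826 x MAD`, the MAD-based robust equivalent of three standard
deviations — a plain SD estimate would be corrupted by the very outliers
the filter is meant to remove.  Edge windows are clipped to the record
bounds.

**Band-pass.** Fourth-order Butterworth, 0.5–4.0 Hz, applied
forward–backward (`sosfiltfilt`) so cycle landmarks are not shifted in
time.  The amplitude gain of the double pass equals the squared
single-pass magnitude; tests verify it against the closed-form
bilinear-prewarped Butterworth response at six probe frequencies.

**Cycle detection.** Systolic upslopes are maxima of the first
derivative separated by a 0.25 s refractory period.  The height
threshold is robust — `median(d) + 2 x 1.4826 x MAD(d)`, capped at a
third of the derivative maximum — because motion artifacts can carry
derivatives an order of magnitude above the cardiac upslope and would
otherwise mask it.  A steep rise running into the record boundary has
no interior derivative maximum and is recovered explicitly.  The
diastolic valley is the signal minimum in a short window (35% of the
median upslope gap) immediately before each upslope; anchoring the
search there, rather than taking the global minimum between peaks,
prevents an artifact in the preceding beat from capturing the valley.
Cycles outside 0.25–2.0 s (30–240 bpm) are discarded, as are
record-edge cycles whose duration deviates more than 25% from the
interior median (filtering transients distort the first and last
fractions of a second).

**Template screening.** Cycles are linearly resampled to 64 points.
Non-overlapping windows of 10 consecutive cycles are screened in two
passes: the first pass scores each member against a *consensus*
template — the member with the highest mean correlation to its peers,
averaged with every member correlating at least 0.8 with it.  Noise
bursts and waveform inversions do not cohere with each other, so the
clean cycles form the winning cluster even when half a window is
corrupted; a plain mean template would be diluted by large-amplitude
artifacts and defeat its own purpose.  The second pass rebuilds the
template as the mean of the first-pass survivors (when at least three
survive) and re-scores, so the reported reference waveform is an
average of plausible cycles.  Three metrics gate each cycle, all
configurable: Pearson correlation with the template (keep if >= 0.9),
Euclidean distance between the unit-norm waveforms (keep if <= 0.5;
scale-invariant, 0 for identical shapes, bounded by 2), and relative
deviation from the window's median duration (keep if <= 0.25).

## Blood-pressure estimation

Each kept cycle yields 31 features: 13 temporal (duration, upstroke and
diastolic times, peak amplitude, widths at 25/50/75% amplitude by
linear interpolation, area, first/second-derivative extrema, upstroke
ratio), 7 spectral over a window extending 5 s beyond each cycle end
(total 0.5–4 Hz power, three relative band powers that sum to one,
dominant frequency, spectral entropy, harmonic ratio), 10 accelerometer
statistics over the same window (per-axis and magnitude mean/SD, motion
intensity, a validity flag that is zero when no accelerometer data
exist), and heart rate.  Spectral windows clipped at record boundaries
must retain at least 2 s.

Cycles are paired with the nearest cuff reading within +/-30 s (earlier
reading on ties); unpaired cycles are dropped.  Regressors (dummy mean,
decision tree, kNN with k=5, RBF-kernel SVR, random forest with 500
trees) are fitted separately for SBP and DBP inside a pipeline whose
standardization statistics come from the training side only.
Predictions are clipped to 30–300 mm Hg.

Two protocols: LOSO (one fold per subject, subject sets disjoint by
construction) and personalized 70/30 (readings sorted chronologically,
the first `floor(0.7 n)` readings and all their cycles train; every
training timestamp strictly precedes every test timestamp, which the
harness asserts).  Both report MAE per fold alongside the dummy
baseline, and aggregate MAE as the unweighted mean over folds.

## Activity recognition

The stream is low-pass filtered at 10 Hz (noise), the gravity component
is a 0.3 Hz low-pass of the denoised signal, and the dynamic component
is their difference — an implicit 0.3–10 Hz band-pass.  Rates below
20 Hz are rejected (the 10 Hz cutoff needs headroom below Nyquist).
Non-overlapping 2-s windows (trailing partial dropped) yield a fixed
65-feature vector: for each of the three dynamic axes and the dynamic
magnitude — mean, variance, skewness, kurtosis, min, max, range, RMS,
IQR, MAD, accumulated velocity change `integral |a| dt` and mean squared
acceleration (48); gravity means and inclination angles per axis (6);
peak count (prominence >= 0.05 g) and mean-crossing count per channel
(8); and the three inter-axis correlations.  Zero-variance channels
define skewness = kurtosis = correlation = 0 to avoid NaN propagation.
The classifier is a 300-tree random forest over the closed 10-activity
set; LOSO evaluation accumulates one confusion matrix over all folds
and derives per-class precision/recall/F and macro averages from it,
excluding classes without true instances from the macro.

## Psychological profiles

Audio is DC-removed and RMS-normalized (reference 0.1), making all
speech features gain-invariant.  Frames are 25 ms with a 10 ms hop.
Pitch uses the normalized autocorrelation peak in the 50–500 Hz lag
band with a 0.3 voicing threshold; unvoiced frames are excluded from
pitch statistics, and a segment with no voiced frame flags its pitch
statistics as missing.  Thirteen MFCCs come from a 26-filter mel bank
and an orthonormal DCT-II (coefficient 0 discarded).  Smoothed energy
is log frame energy (dB) passed through a 5-frame edge-replicating
moving average.  Each of the 15 base features is summarized by mean,
SD, range, max and min (75 values).  Cardiac features are mean heart
rate and RMSSD (intervals outside 250–2400 ms rejected with a warning;
fewer than two remaining is an error).  Speech and cardiac features are
fused early into one vector — the classifier contract ("features are
fed into a model") permits either; early fusion is the simpler design.
Classifiers: Gaussian naive Bayes, an MLP, a random forest and an RBF
SVM (default), evaluated LOSO; the majority baseline's accuracy equals
the largest class share of the evaluated instances.  The
profile-to-principle lookup is fixed: motivated → cognitive
consequences of forced compliance, anxious → free choice, depressed →
effort justification.

## Well-being recommender

The feeling-of-health model is a 100-tree random forest (the default of
the toolkit family the original system used); holdout accuracy is
reported on a stratified 80/20 split and the returned model is the one
fitted on the 80% so the reported accuracy describes exactly it.

Non-modifiable features are *correlated* when their largest absolute
Pearson correlation with any modifiable feature reaches the threshold
(default 0.3); constant features are uncorrelated with a warning.  Each
correlated feature gets an OLS model on all modifiable features
(pseudoinverse under rank deficiency, with a warning).  Propagation is
residual-preserving — `new_f = old_f + model(modified) -
model(original)` — so the zero modification is an exact identity; the
alternative (overwriting with the model prediction) would modify
records even at zero delta.

The two objectives are the *modification volume*, defined here as the
range-normalized absolute change `sum_i |delta_i| / range_i` with
ranges taken from the training data (unit-free comparability across
features), and the number of modified features.  NSGA-II runs with
population 100, 100 generations, simulated binary crossover (eta=15,
p=0.9), polynomial mutation (eta=20, p=1/n) — and, because a
continuous genome almost never produces exact zeros, the genome pairs
each delta value with an on/off mask bit (uniform crossover, 1/n
bit-flip mutation), so solutions touching few features are exactly
representable.  Admissibility (the classifier predicts "good" after
propagation) is enforced by constrained domination: admissible
candidates dominate inadmissible ones outright.  An archive keeps the
best volume seen per `n_changed` (with an integer second objective this
*is* the Pareto archive); the returned front is its non-dominated
subset, every member admissible.  A record already predicted good
returns an empty front with status `already-good`; an exhausted search
returns `no-solution`, mirroring the minority of cases where no
suitable modification exists within bounds.

Note that on a front over (volume, n_changed) at most one solution per
`n_changed` value can survive dominance, so when either of two features
alone can flip the prediction the front carries the cheaper
single-feature fix (the other is dominated).

## Synthetic data

The generators are statistical stand-ins, not physiologically validated
simulations; they exist so every method is testable without any data
download, and they emit ground truth sufficient to verify each result.

**PPG sessions.** Each beat is a two-lobe pulse: a half-sine systolic
rise over the leading fraction `u` of the cycle, an exponential
diastolic decay with constant `tau` (cycle fraction) plus a small
dicrotic bump.  The documented, invented morphology mapping is
`u = 0.24 - 0.0015 (SBP - 110)` and `tau = 0.42 - 0.003 (DBP - 70)`
(clipped to [0.08, 0.45] and [0.10, 0.80]), so waveform features carry
blood-pressure information by construction.  Defaults define the study
conditions: 4 h at 64 Hz, heart rate 70 bpm, Gaussian waveform noise SD
0.05 (5% of the unit pulse), 2 artifacts per minute (whole-beat noise
bursts of SD 1.5 or inversions), cuff readings every 30 min.  The
default SBP/DBP trajectories sweep their full ranges (112–150 /
68–92 mm Hg) twice during the first 70% of the session and keep
fluctuating inside those ranges afterwards: the personalized protocol
trains on the chronologically earliest readings, and tree ensembles
cannot extrapolate beyond the training target range, so a session whose
late readings left the early range would make the protocol ill-posed
rather than hard.  `gen_cycle_set` emits pre-segmented cycles (2%
duration jitter) with a corruption mask for screening tests.  What the
generator does **not** emulate: baseline wander, sensor saturation,
pulse-amplitude variation with contact pressure, HR variability within
a segment, or any real vascular physiology — passing tests show the
pipeline recovers structure the generator put in, not clinical
accuracy.

**Activity sessions.** Per-class regimes combine a wrist orientation,
an oscillation frequency and per-axis amplitude, sensor noise, and a
duty cycle for intermittent gestures (rest: gravity + 0.01 g noise;
walking: 2 Hz arm swing at 0.25 g; running: 3 Hz at 0.8 g; eating:
0.8 Hz duty-cycled rotations; chores: strong noisy 1.5 Hz bursts;
etc.).  Regimes are linearly separable by design; real inter-person
variability is not modelled beyond the seed.

**Well-being tables.** Six features; humidity is drawn with a
configurable correlation to temperature (default 0.7), SBP is mildly
inversely driven by temperature, DBP follows SBP — so the partition has
correlated features to find.  Labels follow a declarative pandas
expression (default `good iff temperature <= 25.5 and humidity <= 62`),
flipped with a configurable probability (noise).

**Profiles.** Per-class multivariate normals over six
psychophysiological summary features (documented means; e.g. anxious:
HR 88 bpm, RMSSD 20 ms; depressed: low, flat pitch and low energy).  A
`separation` factor scales class-mean offsets (0 removes all signal).
Interval series are built as base + i.i.d. jitter with
`sigma = RMSSD_target / sqrt 2`, which makes the expected RMSSD equal
the target.

## Numerical choices and degenerate inputs

Ties in ground-truth pairing go to the earlier reading.  Flat cycles
raise an undefined-feature error; silent audio and zero-variance
signals raise degenerate-signal errors; schema mismatches between a
fitted model and a feature table are contract errors, not silent
reindexing.  All stochastic components take explicit integer seeds and
identical seeds give bit-identical outputs (asserted in tests).  CSV
exchange uses comma separation, UTF-8, `.` decimals and seconds as
floats; CLI runs write a manifest with config hash, seed, version and
SHA-256 digests of all inputs and outputs.

## Problem sizes used in the shipped verification

The test and acceptance runs use: 10-s noise-free pulse trains at
40–180 bpm for detection counts; a 200-cycle set with 25% corruption
for screening; one 4-h personalized BP session (generator defaults);
six synthetic subjects with five activity regimes (200 s each); 30
profile subjects (10 per class); a 500-record well-being table with 2%
label noise, with the recommender evaluated on a seeded 25-record
sample of the bad-predicted records.  These sizes were chosen so the
entire verification runs in a few minutes while keeping every
statistical margin wide (the observed rates sit far from their
thresholds).

## Known limitations

No clinical-accuracy claim is made or testable here (no AAMI/BHS
grading); the BP features assume the band-passed waveform, which
attenuates fast systolic detail at low sampling rates; eating-like and
hand-activity regimes are caricatures of genuinely hard classes;
speech features are computed on clean synthetic tones in tests, not
telephone-band speech; the recommender's propagation model is linear
and makes no causal claim about interventions.
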