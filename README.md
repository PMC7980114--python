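# pulseman

Wrist-sensor patient monitoring and data-driven decision support for
chronic heart-failure telehealth, as a tested Python toolkit:

* **Cuffless blood-pressure estimation** from single-channel wrist
  photoplethysmography (PPG): zero-mean/unit-variance normalization, a
  Hampel outlier filter (local median, 3 x scaled-MAD threshold), a
  fourth-order zero-phase Butterworth band-pass (0.5–4.0 Hz),
  derivative-based cardiac-cycle detection, and sliding-window template
  screening that discards individual bad cycles inside otherwise good
  segments.  Kept cycles yield temporal-morphology, spectral (10-s
  context window), accelerometer and heart-rate features fed to
  regression models (dummy-mean baseline, decision tree, kNN, SVR,
  random forest) for SBP and DBP (mm Hg).  Evaluation is
  leave-one-subject-out (LOSO) for general models and a chronological
  70/30 split at cuff-reading granularity for personalized models, both
  reporting MAE against the dummy baseline.
* **Physical-activity recognition** from wrist tri-axial acceleration:
  10 Hz denoising, 0.3 Hz gravity separation, 2-second windows, a fixed
  65-feature vector (moments, orientation, velocity/energy proxies,
  peak and mean-crossing counts, inter-axis correlations) and a random
  forest over ten everyday activities, evaluated LOSO with per-class
  precision/recall/F-measure.
* **Psychological-profile recognition** (motivated / anxious /
  depressed) from speech prosody (pitch, 13 MFCCs, smoothed energy —
  each summarized by mean/SD/range/max/min) fused with heart rate and
  RMSSD, plus the fixed mapping from profile to the Festinger
  cognitive-dissonance principle used to phrase motivational messages.
* **Well-being recommender**: a random-forest feeling-of-health
  classifier, a modifiable / correlated / uncorrelated feature
  partition with per-feature linear propagation models, and an NSGA-II
  search for minimal admissible modifications, minimizing the
  range-normalized modification volume `sum_i |delta_i| / range_i` and
  the number of modified features, subject to the classifier predicting
  "good" after the change.
* **Synthetic data generators** for all of the above, with ground
  truth: PPG whose per-cycle morphology is a documented deterministic
  function of the underlying SBP/DBP, per-activity accelerometer
  regimes, rule-labelled well-being tables, and per-profile
  psychophysiological distributions.

No public dataset accompanies the original system, so the generators
define the study conditions under which every method is verified.

## Worked example

Simulate ten minutes of wear, screen the PPG, and ask the recommender
about a record with a bad predicted feeling of health:

```sh
$ pulseman synth ppg --seed 1 --out session --duration 600
$ pulseman ppg preprocess --in session/ppg.csv --out screened
707 cycles, 658 kept
```

707 valley-to-valley cardiac cycles were detected in the 600-s record
(70 bpm plus ~20 injected motion artifacts); template screening kept
658 and flagged the artifact-bearing rest.  `screened/cycles.csv` lists
each cycle's landmarks, template correlation, normalized distance and
keep verdict.

```sh
$ pulseman synth wellbeing --seed 1 --out wb
$ pulseman dss recommend --records wb/wellbeing.csv --record-id 1 --seed 1 --out reco
{
  "status": "ok",
  "n_solutions": 1,
  "model_holdout_accuracy": 94.0
}
$ cat reco/front.csv
solution_id,temperature,humidity,volume,n_changed
0,-1.9200636603521737,-19.235615294970756,0.3318586619890658,2
```

Record 1 (temperature 27.3 °C, humidity 80.5 %RH) is predicted "bad" by
the feeling-of-health model (94% holdout accuracy).  The search found
one Pareto-optimal admissible modification: lower the temperature by
1.9 °C **and** the humidity by 19.2 percentage points (both are too
high for a single-feature fix here), a total normalized volume of 0.33.
Records with only one feature out of range typically receive
single-feature recommendations.

Every command writes a `manifest.json` (config hash, seed, package
version, input/output SHA-256 digests) so any run can be reproduced and
verified bit-for-bit.

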