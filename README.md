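# threadmotion

Head-orientation monitoring and classification from two crossed
strain-sensing threads worn on the back of the neck.

Two carbon-coated elastic threads are taped in an "X" — one as "/", one as
"\\" — and their impedance is streamed at 1 kHz. Rotating the head
(horizontal axis) stretches one thread while relaxing the other, so the two
channels move in opposite directions; flexing the head up or down (vertical
axis) drives both together. From that structure the head position can be
classified into nine orientations: left, front-left, front, front-right,
right along the horizontal axis and down, front-down, front, front-up, up
along the vertical axis (front is shared).

`threadmotion` implements the complete processing chain as a tested Python
library plus CLI:

1. **Calibration** — from a recording of repeated full-range excursions,
   estimate per channel the settled front-facing *baseline* (median of the
   most populous cluster of flat-plateau means), and the *calibrated
   max/min* (global extremes of the filtered signal).
2. **Filtering** — causal moving average, length 120 samples.
3. **Normalization** — piecewise about the baseline: values above it are
   scaled by (max − baseline), values below by (baseline − min), so
   {min, baseline, max} → {−1, 0, +1} and stretch/relax excursions are
   weighted equally despite the thread's asymmetric response.
4. **Segmentation** — overlapping windows of 550 samples (0.55 s) with a
   250-sample overlap (hop 300); window labels by majority vote.
5. **Features** — per window: the two channel means μ_/ and μ_\\, their
   difference Δμ = μ_/ − μ_\\, the Pearson correlation ρ between channels,
   and the per-channel min–max swings δ_/ and δ_\\ (six predictors, so the
   Gaussian-SVM kernel scale √6 ≈ 2.4).
6. **Classification** — nine configurations: linear / quadratic / cubic /
   Gaussian-kernel SVM (one-vs-one), Gaussian and kernel naive Bayes, and
   cosine / cubic / weighted (1/d²) 10-nearest-neighbour classifiers, all
   on features standardized with training-split statistics.
7. **Evaluation** — 100 rounds of random 75/25 train/test splitting shared
   across all nine classifiers; averaged accuracies and pooled confusion
   matrices.

No public dataset of this sensor exists, so the package ships a first-class
synthetic-data generator (`threadmotion.synthetic`) that emulates the
documented signal structure — per-orientation levels, anti-correlated
horizontal vs correlated vertical channels, smooth ramps through the
intermediate positions, drift, settling transients, spontaneous jumps and
common-mode micro-motion — with retrievable ground truth for every
parameter-recovery test.

## Worked example

```python
from threadmotion import (
    GeneratorConfig, MotionScript, calibrate, extract_feature_table,
    generate_calibration_recording, generate_recording, repeated_holdout,
)
from threadmotion.features import feature_matrix

config = GeneratorConfig(seed=1)
profile = calibrate(generate_calibration_recording(config))
recording = generate_recording(MotionScript.setup_protocol(), config=config)
table = extract_feature_table(recording, profile)   # 400 labeled windows
X, y = feature_matrix(table)
report = repeated_holdout(X, y, reps=100, train_frac=0.75, seed=2)
print(report.summary())
```

prints

```
Repeated holdout: 100 reps, 75% train, 400 segments, seed 2
classifier     averaged testing accuracy
cosine_knn     92.1%
cubic_knn      93.1%
weighted_knn   96.0%
linear_svm     95.8%
quadratic_svm  96.5%
cubic_svm      96.1%
gaussian_svm   94.5%
kernel_nb      91.5%
gaussian_nb    92.5%
```

Each line is the mean over the 100 rounds of that configuration's test-set
accuracy on the 100 held-out windows. On synthetic data every configuration
stays above ~90%, and inspecting `report.confusions` shows that nearly all
errors confuse *axis-adjacent* orientations (e.g. front-right with right),
the signature error structure of this sensor.

The same workflow is available from the shell:

```sh
threadmotion simulate --config config.yaml --calibration --out cal.csv
threadmotion simulate --config config.yaml --out motion.csv
threadmotion calibrate cal.csv --out profile.json
threadmotion run motion.csv --profile profile.json --out features.csv
threadmotion evaluate features.csv --reps 100 --out report.json
threadmotion train features.csv --classifier linear_svm --out model.joblib
threadmotion predict-stream motion.csv --model model.joblib --profile profile.json
```

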