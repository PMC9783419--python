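# rehabscore

Wearable-sensor movement scoring and Fugl-Meyer mapping for stroke
rehabilitation assessment.

## The problem

Clinical motor-function assessment after stroke relies on physician-scored
scales such as the Fugl-Meyer assessment (FMA): 33 upper-limb and 17
lower-limb motor items, each scored 0/1/2, giving totals of 0-66 (upper),
0-34 (lower) and 0-100 (grand). Scale assessment is slow (30-45 min),
subjective, and coarsely graded. An alternative is to instrument the
patient with wearable inertial and flex sensors, have them perform a fixed
battery of assessment movements, and score each movement automatically by
comparing the recorded signals against a clinician's standard execution.

`rehabscore` implements that pipeline end to end, for engineers and
rehabilitation researchers who want a tested, reproducible reference
implementation:

1. **Preprocessing** — centered moving-average filtering and
   effective-movement-cycle extraction from the angular-speed magnitude.
2. **Template matching** — dynamic time warping (DTW) with the squared
   Euclidean local distance d(x, y) = ||x − y||². The cumulative matching
   distance follows

       D(i, j) = d(x_i, y_j) + min(D(i−1, j−1), D(i−1, j), D(i, j−1))

   with DTW(X, Y) = D(M, N); warping paths are monotone and continuous,
   so sequences of different speed/length compare meaningfully.
3. **Movement scoring** — per feature (angle, angular velocity,
   acceleration, finger flexion), the DTW distance X_i is normalized by
   X_max (the distance of *no movement at all*; X_min = 0 is the
   clinician's own movement) and fused with entropy-method weights δ_i:

       deviation = 100 · Σ_i δ_i · clip(X_i / X_max,i, 0, 1)

   The complement `quality = 100 − deviation` (100 = perfect) is the
   movement score used downstream; both orientations are exposed.
4. **FMA mapping** — an RBF-kernel support vector regression maps the 32
   movement scores to physician-consistent FMA totals (three independent
   models: total, upper, lower), with seeded 5-fold grid search.
5. **Agreement analysis** — calibration regression (intercept, slope, 95%
   CI, R², p), Bland-Altman deviation and relative-deviation analysis with
   mean ± 1.96 SD limits of agreement, and a Student's t comparison of
   assessment durations.

Because no patient recordings are distributed, the package ships a
first-class synthetic cohort generator (`synthcohort`): raised-cosine
movement templates, severity-graded signal degradation (amplitude loss,
slowing, tremor, sensor noise), a latent-trait physician rater model for
the FMA items, and realistic assessment durations.

## Worked example

```python
import numpy as np
import rehabscore as rs
from rehabscore.fma_map import records_from_cohort, train_mapping, predict_fma
from rehabscore.agreement import build_report

cohort = rs.generate_cohort(120, seed=1)                 # 120 simulated subjects
templates = rs.build_battery_templates(seed=1)           # 32 clinician templates
scores, templates = rs.score_cohort(cohort, templates)   # DTW + entropy weights
records = records_from_cohort(cohort, scores)

rng = np.random.default_rng(1)
idx = rng.permutation(120)
train, test = [records[i] for i in idx[:80]], [records[i] for i in idx[80:]]
models = {t: train_mapping(train, target=t, seed=1)
          for t in ("total", "upper", "lower")}
for r in test:
    r.system_total = predict_fma(models["total"], r)
    r.system_upper = predict_fma(models["upper"], r)
    r.system_lower = predict_fma(models["lower"], r)

report = build_report(test,
                      system_times=[s.system_time for s in cohort],
                      physician_times=[s.physician_time for s in cohort])
reg = report.regression["total"]
dev = report.deviations["total"]["deviation"]
print(f"slope {reg['slope']:.3f}, R^2 {reg['r_squared']:.4f}")
print(f"deviation mean {dev['mean']:.2f}, SD {dev['sd']:.2f}, "
      f"{dev['within_limit_percent']:.1f}% within limits")
```

This prints (seed 1):

```
slope 1.012, R^2 0.9948
deviation mean -0.83, SD 3.02, 92.5% within limits
```

i.e. on 40 held-out simulated subjects the system's predicted FMA total
tracks the simulated physician total with near-unit slope and R² ≈ 0.99,
and 92.5% of the score deviations fall inside the 95% limits of agreement
— the agreement structure the protocol is designed to measure.

The same chain is available from the shell:

```sh
rehabscore simulate --n 120 --seed 1 --out cohort/
rehabscore score    --data cohort/
rehabscore train    --scores cohort/movement_scores.csv \
                    --labels cohort/labels.csv --target total --seed 1 \
                    --out model_total.json
rehabscore predict  --model model_total.json \
                    --scores cohort/movement_scores.csv --out predictions.csv
```

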