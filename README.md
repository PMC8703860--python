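# stressfs

Hybrid **mRMR–PSO–SVM** feature selection for EEG-based mental-stress
recognition.

Wearable-EEG stress monitors must work with few channels and a compact
feature set. The usual desk pipeline extracts a large multi-domain feature
vector from every epoch — time-domain descriptors, band powers,
time-frequency measures and connectivity — and then has to cope with heavy
redundancy and irrelevance in that vector. `stressfs` implements a hybrid
selector for this problem, aimed at researchers building two-class
(stress vs rest) EEG classifiers:

1. **Preprocessing** — zero-phase FIR band-pass (0.5–35 Hz), common average
   reference, fixed-length epoching against a task schedule.
2. **Feature extraction** — per channel: Hjorth activity/mobility/
   complexity, peak-to-peak amplitude, line length, kurtosis, skewness,
   relative (and absolute) power in θ [4–8), α [8–12), σ [12–15),
   low-β [15–20) and high-β [20–30) Hz, Welch spectral entropy, Katz
   fractal dimension; across channel pairs: phase-locking value (PLV).
   Fused dimensionality is `20·C + C(C−1)/2` for `C` channels
   (161 / 188 / 86 features for 7 / 8 / 4 channels), z-scored column-wise.
3. **Filter stage (mRMR)** — greedy ranking by the F-test correlation
   quotient: `FCQ(Xi) = F(Xi, y) / mean_{Xj∈S} |ρ(Xi, Xj)|`, i.e. maximize
   one-way ANOVA relevance while minimizing mean absolute Pearson
   correlation to the already-selected set.
4. **Wrapper stage (binary PSO + SVM)** — a particle swarm over a mixed
   space: one sigmoid-binarized coordinate per pooled feature plus two
   continuous coordinates, log₂C and log₂γ, of the RBF-SVM. Velocities
   follow `V′ = wV + c₁r₁(pbest−X) + c₂r₂(gbest−X)`, positions `X′ = X+V′`;
   fitness is the cross-validated F-measure of the stress class.
5. **Evaluation** — stratified 80/20 split, final SVM retrained on the full
   training partition with the selected mask and optimized (C, γ), scored
   once on untouched test rows (precision, recall, F-measure, accuracy).

Synthetic generators (two-class oscillatory EEG with band-power and
phase-coupling contrasts; planted informative/redundant/noise feature
tables) make every stage testable without any dataset download.

## Worked example

```python
from stressfs import (PlantedTableSpec, generate_table, PipelineConfig,
                      SwarmConfig, mrmr_pso_svm, signal_recovery)

table, truth = generate_table(PlantedTableSpec(seed=1000))   # 400 x 100, 5 planted signals
cfg = PipelineConfig(swarm=SwarmConfig(n_particles=20, n_generations=40,
                                       patience=12), seed=0)
result = mrmr_pso_svm(table, cfg)
print("selected", result.selected_count, "of", table.n_features, "features")
print("held-out accuracy", round(result.metrics.accuracy, 3),
      "F-measure", round(result.metrics.f_measure, 3))
print("signals recovered", signal_recovery(result.mask, truth)[1], "/ 5")
```

Output:

```
selected 33 of 100 features
held-out accuracy 0.863 F-measure 0.861
signals recovered 5 / 5
```

The selector kept 33 of 100 columns (all five planted signal groups among
them) and classified the held-out 20% at 86% accuracy, close to the Bayes
limit of the generating model (~87% at effect size 1.0 per informative
feature).

The same flow is available from the shell:

```bash
stressfs simulate table --seed 1 --out table.csv
stressfs rank --features table.csv --pool 60 --out ranking.json
stressfs select --features table.csv --ranking ranking.json --seed 7 --out result.json
stressfs evaluate --features table.csv --seed 7 --report report.json
stressfs extract --input rec.edf --window 20 --schedule schedule.csv --out features.csv
```

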