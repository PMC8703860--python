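# Methods

This note documents the models, conventions and design choices behind
`stressfs`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## Preprocessing

The band-pass is a windowed-sinc FIR (Hamming window), pass band
0.5–35 Hz by default, with the order chosen for a ≈1 Hz transition band
(`numtaps ≈ 3.3·fs/Δf`, forced odd). It is applied forward–backward
(`filtfilt`), so the response is zero-phase and epoch boundaries are not
shifted; stop-band attenuation is doubled by the two passes. Signal
extension uses even reflection, which keeps the extension continuous for
oscillatory signals and keeps edge transients small; signals shorter than
three filter lengths are rejected rather than filtered badly. The common
average reference subtracts the instantaneous cross-channel mean; both
operations are linear and commute to numerical precision.

Epochs are half-open windows `[start, start + window_s)` with 0-based
sample indexing, cut against an explicit `(start_s, label)` schedule. The
default window of 20 s matches the rest-block length of typical
block-design stress protocols and the shortest window at which the slowest
analysis band (θ, 4 Hz) still contains dozens of cycles; it is
configurable, and nothing in the pipeline assumes a particular length
beyond the filter-length and 2-cycles-of-4-Hz minima. Artifact removal
(ICA for EOG/EMG) is deliberately out of scope: the library expects
pre-cleaned input from standard upstream tooling.

## Feature roster

Per channel (roster `"full"`, 20 descriptors): Hjorth activity, mobility,
complexity; peak-to-peak amplitude; line length (sum of absolute first
differences); kurtosis and skewness; relative power in θ [4–8), α [8–12),
σ [12–15), low-β [15–20), high-β [20–30) Hz; the five absolute band powers
and broadband (4–30 Hz) total power; Welch spectral entropy; Katz fractal
dimension. Roster `"literal"` drops the absolute-power block (14
descriptors); roster `"plv"` keeps only connectivity. Connectivity
contributes one phase-locking value per unordered channel pair, computed
from analytic-signal (Hilbert) phases of the broadband signal; per-band
PLV is available as an option but off by default. Fused dimensionality in
full mode is `20·C + C(C−1)/2`, giving 161, 188 and 86 features for 7-,
8- and 4-channel montages. The absolute-power augmentation is the
package's choice of the six extra per-channel descriptors that complete
the 20-per-channel budget implied by those totals; the count, not the
composition, is the hard constraint.

Conventions that matter:

- **Population moments everywhere** (divide by N), so Hjorth activity is
  `var(x)`, kurtosis is the non-excess `m₄/σ⁴` (≥ 1, → 3 for a Gaussian).
  Mobility is computed on first differences without sampling-rate scaling,
  so for a tone of frequency f it equals `2·sin(πf/fs)`; this is a
  monotone proxy of mean frequency at fixed fs, which is all a
  within-study classifier needs.
- **Relative powers** integrate the Welch PSD over half-open bands and
  divide by the power in the union of the five bands (4–30 Hz), so the
  five values always sum to exactly 100%.
- **Welch settings**: Hamming window, segments of `min(4 s·fs, len(x))`
  samples, 50% overlap. Spectral entropy uses the natural log of the PSD
  normalized over 4 Hz up to `min(35, 45, Nyquist)` Hz — the upper edge is
  capped at the effective filter bandwidth, since bins beyond it hold only
  stop-band leakage. Note that with a Hamming window a pure tone's energy
  spreads over the window main lobe, so the degenerate-spectrum limit of
  the entropy is ≈0.76 nats (≈16% of log K for 10-s epochs at 256 Hz),
  not 0; white noise reaches ≥ 98% of log K.
- **Katz dimension** treats the waveform as a planar curve of points
  `(i, xᵢ)` with unit time step: `L` = curve length, `d` = maximal
  distance from the first point, `n` = number of steps,
  `D = log₁₀(n)/(log₁₀(d/L) + log₁₀(n))`. This is the convention under
  which a straight line gives exactly 1 and every other curve a finite
  value > 1; the amplitude-only variant (`L = Σ|Δx|`, `d = max|x−x₀|`)
  degenerates (division by zero / infinite D) on signals whose extent
  equals `1/L`, e.g. a ±1 alternation. A constant signal is a straight
  line under this convention (D = 1); it still fails earlier features
  (zero variance), so flat epochs are dropped during extraction.
- **Missing cells**: an epoch on which any descriptor fails is dropped
  with a warning rather than imputed; extraction errors out only if no
  epoch survives.

Z-scoring is column-wise with population SD; parameters are fitted on
training rows only and applied unchanged to held-out rows. A zero-spread
column raises an error naming the offending feature.

## mRMR ranking

Relevance is the one-way ANOVA F-statistic of a column against the binary
label; redundancy is mean absolute Pearson correlation to the
already-selected set; the greedy criterion is the quotient
`FCQ = F / mean|ρ|`. The first pick uses relevance alone (the mean over an
empty set is undefined — the standard convention). Ties break toward the
lower column index, making the ranking fully deterministic. Two guards
keep the ordering well defined: perfect separation (zero within-class
variance with a real mean gap) maps to a large finite sentinel F = 1e12,
and the redundancy denominator is floored at 1e-12, so a feature nearly
orthogonal to the selected set gets a very large but finite quotient. A
consequence worth knowing: FCQ can rank an irrelevant-but-orthogonal
column above a highly relevant near-duplicate, because the quotient
explodes as mean|ρ| → 0. That is a property of the criterion, not a bug;
the wrapper stage downstream corrects for it. The default pool handed to
the wrapper is `ceil(0.6·m)` (configurable); the unit tests verify the
greedy choice against exhaustive per-step evaluation.

## Binary PSO with SVM co-optimization

Search space: one latent coordinate in [0, 1] per pooled feature plus
log₂C ∈ [−5, 15] and log₂γ ∈ [−15, 3] (the standard RBF grid bounds),
optimized jointly. Velocity update `V′ = wV + c₁r₁(pbest−X) + c₂r₂(gbest−X)`
with c₁ = c₂ = 2, clamped to ±v_max with v_max = 6 (the sigmoid is
effectively saturated beyond that). Positions move by `X′ = X + V′`;
continuous dims are clamped to their ranges; each mask bit is realized
stochastically as 1 iff `r < sigmoid(V′)` — the classic transfer-function
binarization, since plain PSO is not defined on a binary space. Default
budget is 50 particles and 200 generations with plateau termination
(no gbest improvement > 1e-6 for 30 generations); the simulation
benchmarks use smaller budgets (≈20 particles, ≈40 generations), which the
enumeration check shows lose at most ~1% fitness at pool sizes they can
be compared on.

The inertia weight is data-adaptive by default: the mean mutual
information (10 equal-frequency bins, natural log) between each pooled
feature and the label, clipped to [0.4, 0.9]. This reads the "inertia
from the information content of the ranked subset" idea as a concrete,
stable rule: weakly informative pools get the floor 0.4 (fast
exploitation), strongly informative pools drift higher. A fixed scalar w
can be passed instead.

Fitness is the mean F-measure of the stress class (positive = 1) under
stratified 3-fold cross-validation on the training partition, with folds
fixed per run so the swarm optimizes a deterministic objective. An empty
mask scores 0 without training; a degenerate single-class training fold is
resampled once and then scored 0. The returned mask is lifted from pool
coordinates to original feature indices and is never empty (a fully-empty
gbest falls back to the top-ranked feature). The gbest trace is monotone
non-decreasing by construction and asserted on every run.

## Pipeline and evaluation

`mrmr_pso_svm` wires the stages with a strict leakage discipline:
stratified 80/20 split (seed-reproducible; subject-independent grouping
optional via per-row subject ids) → z-score fitted on train → mRMR on
train → swarm on train → final RBF-SVM retrained on the full training
partition with the best mask and (C, γ) → one evaluation on the untouched
test rows. Retraining on the full training partition before the single
held-out evaluation is the package's choice where the procedure's
retraining scope was open. Metrics satisfy the confusion-matrix
identities exactly, with a 0-and-flagged convention for empty
denominators. Affective self-report labeling is provided for 1–9
valence/arousal scales: calm iff arousal < 4 and 4 < valence < 6, stress
iff arousal > 5 and valence < 3, everything else unlabeled and excluded.

## Synthetic data: what it does and does not show

`generate_eeg` builds epochs as sums of band-limited Gaussian oscillations
(filtered white noise per band — not pure tones, so PSD features have
realistic spread) plus broadband sensor noise, with 1/f-like base
amplitudes (θ 1.0, α 1.5, σ 0.8, low-β 0.7, high-β 0.6 µV RMS). Class
contrasts: per-band power ratios (default α×0.6, high-β×1.4 — the classic
frontal alpha-suppression / beta-increase stress signature) and shared
oscillatory processes mixed variance-preservingly into coupled channel
pairs (default coupling 0.8), which raises broadband PLV by ≈0.3.

`generate_table` plants informative columns (class-shifted Gaussians,
default standardized separation 1.0 per column — five such columns put the
Bayes accuracy near 0.87, inside the 77–94% band typical of published
stress classifiers), redundant copies (`ρ·parent + √(1−ρ²)·noise`,
default ρ = 0.95, round-robin over parents) and independent noise columns,
then shuffles columns and returns the ground-truth index sets. Recovery
is scored at the signal-group level (an informative column or any of its
copies), because at ρ = 0.95 parent and copy are near-exchangeable
carriers of the same signal and an F-measure-only fitness has no reason to
prefer one.

What passing these benchmarks shows: the ranking follows its defining
criterion exactly; the swarm reaches the enumeration optimum at small
scale; planted signal is found reliably; nothing leaks from test rows
(zero-signal tables stay at chance). What it does not show: behaviour
under real EEG nuisance structure — artifacts, non-stationarity,
inter-subject variability, volume-conduction-inflated PLV — or any claim
about absolute accuracies on real recordings. One honest negative finding
is worth recording: at the default effect size the all-features RBF-SVM
baseline also operates near the Bayes ceiling of the planted model
(redundant copies effectively average feature noise inside the kernel),
so removing noise columns buys little held-out accuracy there, and the
head-to-head comparison against that baseline is close to a tie decided
by the 80 test rows.

## Numerical and degenerate-input policy

Invalid bands (above Nyquist, empty), constant signals where a feature
divides by zero, single-channel connectivity, empty schedules, mixed
labeled/unlabeled schedules, single-class labels, zero-spread columns,
overlapping train/test indices and invalid swarm configurations all raise
typed errors early rather than propagating NaNs; every feature value that
is returned is finite. All simulations and splits are reproducible from
integer seeds; the pipeline derives its split and swarm seeds from one
master seed via `numpy` seed sequences.

## Known limitations

- Re-referencing is common-average only; no bipolar/Laplacian schemes.
- No streaming/online filtering; recordings are processed in memory.
- PLV is broadband by default; per-band PLV multiplies the connectivity
  block and is off by default.
- The mutual-information inertia rule is one concrete reading of an
  ambiguous prescription; a fixed w ∈ (0, 1.5) can always be supplied.
- Multiclass stress levels are out of scope; labels are binary.
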