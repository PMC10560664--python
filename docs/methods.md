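# Methods

This note documents the models and procedures `gazeload` implements, the
defaults it ships, and the choices made where the design was genuinely open.

## Data model and conventions

All analysis coordinates are normalized to the unit square with the origin
at the top-left of the screen and y pointing down, matching screen-raster
convention and making every geometric module device-independent. Trials
occupy half-open windows `[k·(30+2), k·(30+2)+30)` seconds under the default
schedule (20 trials of 30 s, 2 s gaps); gap samples get no trial label and
enter no metric. Uncaptured samples (`valid = 0`) carry NaN coordinates and
count only in the gaze-capture fraction: missingness is measured exactly
once. The gaze-capture quality criterion is computed per session over
in-trial samples, and exclusion is strict (`fraction < 0.25`); a participant
at exactly 25% is kept.

## AOI metrics

AOI membership is evaluated on the union of the named rectangles, with
half-open membership `[x0, x1) × [y0, y1)` and first-declared-wins naming
for overlap queries. The default rectangles (windshield, rearview mirror,
side mirror) are synthetic fixtures mimicking a dashboard layout; they are
configurable through a JSON file and carry no measured meaning.

"More than ten consecutive" in-AOI samples is read as runs of ≥ 11 samples
(~268 ms at 41 Hz, a plausible fixation floor); the boundary is exposed as
`min_run`. Invalid samples terminate runs — tracker loss is not evidence of
dwell. Fixation duration is (qualifying samples)/(sampling rate), so its
absolute scale is the per-trial dwell time; only directional and relative
statements about durations are meaningful across datasets whose trial
normalization differs. The 6 × 8 grid occupancy is computed per session as
proportions of valid samples, with the closing screen edge folded into the
last row/column.

## Fixation detection and the dispersion index

Fixations are detected with the standard I-DT algorithm: a window grows
while `(max x − min x) + (max y − min y) ≤ 0.03` (normalized units,
roughly the tracker accuracy of 1.25°) and is emitted once it spans
≥ 100 ms; both parameters are configurable. Windows never bridge invalid
samples.

The fixation-distribution index is the median Voronoi cell area of a
trial's fixation centroids, cells clipped to the unit square and normalized
by its area. Clipping uses mirrored-point augmentation (each point
reflected across the four sides), which makes every original cell finite
and exactly equal to the clipped cell; a nearest-neighbour rasterization
oracle arbitrates correctness in the tests. Exactly duplicated centroids
are perturbed by a deterministic 10⁻⁹ jitter; fewer than three fixations
yield a missing value. The index lies in (0, 1], is invariant to point
order, and is larger the more dispersed gaze is.

Two properties of this statistic are worth stating plainly. First, the
clipped cell areas always partition the square, so the index is a relative,
not absolute, dispersion measure: its typical magnitude scales like 1/n
with the number of fixations per trial (~0.1 at ~10 fixations, ~0.01 at the
~85 fixations the default generator produces). Second, it is **not**
monotone under uniform contraction of the point set: a near-collapsed
cluster's cells still partition the whole square into wedge-like sectors,
so strong contraction equalizes areas and can *raise* the median above its
value for the spread configuration. This is intrinsic to any statistic of
the clipped partition areas (the collapse limit depends only on angular
structure). In practice the load manipulation does not contract all
fixations uniformly — it shrinks the spread of background fixations while
AOI-directed fixations keep their extent — and under that mechanism the
index moves in the expected direction, which the simulation tests verify.
Alternative definitions (mean area is constant at 1/n; area skewness is
unbounded) were considered and rejected for violating the larger-=-more-
dispersed contract or the (0, 1] range.

## Synthetic cohort generator

The generator encodes effects at the fixation level so run-length metrics
behave realistically. Each trial alternates fixations (lognormal duration,
mean 0.30 s, shape 0.4) and 0.04 s saccades. A fixation targets the AOI
union with probability `p_aoi(group, condition)` — defaults are the six
reference condition means on the probability scale — choosing windshield /
rearview / side mirror with weights 0.8 / 0.1 / 0.1 (invented; the source
summary only constrains the union) and landing uniformly inside the chosen
rectangle. Otherwise it is a background fixation drawn from an isotropic
Gaussian at screen center with SD `dispersion_scale(group, condition)`,
rejection-sampled to stay inside the square and outside the AOI union (with
a bounded-retry fallback so degenerate configurations still resolve).
Keeping background fixations out of the union is what makes `p_aoi` the
actual sample-level AOI probability: the windshield covers the screen
center, so unconstrained background draws would land inside it and the
configured targets would be unrecoverable.

Centralization under load is modeled as the higher `p_aoi` plus a smaller
background SD. The dispersion defaults (no-load/high-load: control
0.24/0.17, manic 0.23/0.15, depression 0.20/0.13) are modeling choices
fixed by a one-off design-time calibration so the generated cohorts realize
the intended directional structure (index lower under load in every group);
they are not measured values.

Samples are rendered at 41 Hz: centroid + Gaussian jitter (SD 0.005) during
fixations, linear interpolation during saccades, clipped to the square;
each sample is captured with probability 0.9. Participant heterogeneity is
an additive offset on `p_aoi`, shared across trials and conditions, drawn
N(0, 0.10) — the SD matches the reference between-participant spread — and
clamped into [0, 1]. Offsets are centered within each group at cohort level
(mean-exact conditional simulation): the configured cell means are then
cohort-level targets rather than population expectations, which is what
makes a ±2-point recovery check meaningful at n = 11 per group while
preserving the between-participant variance. Quiz answers exist for the 10
high-load trials (3 Bernoulli answers each) with per-group success
probabilities 0.6386 / 0.5848 / 0.5455.

What the generator does **not** emulate: video-content-driven salience,
saccade kinematics, smooth pursuit, blinks/pupilometry, drift or
calibration error, and any correlation between quiz performance and gaze.
Passing recovery tests therefore demonstrates that the pipeline measures
what the generator encodes — not that real gaze data satisfies the model.

## Statistics

Summaries are computed participants-first: trials are averaged within
participant × condition, then group mean and SD (n−1) are taken over
participants, so unequal usable-trial counts cannot skew a group mean.
Pooled (load-collapsed) means are the equal-weight average of the two
condition means, valid because both conditions cover 10 trials. Load
effects are reported in both conventions — absolute difference
(percentage points / index units) and percent of the no-load mean — since
published practice differs by metric (absolute for AOI%, relative for
durations, absolute for the dispersion index).

The mixed model is `metric ~ group + condition` with a random participant
intercept (optional random condition slope behind a flag; residuals are
independent given the intercept). Estimation delegates to statsmodels'
MixedLM (REML). Per-effect tests are Wald contrasts reported on the F
scale with between-within (containment) denominator degrees of freedom:
group — constant within participants — is tested on participant df
(~49 at n = 52), condition on trial-level df. Satterthwaite/Kenward-Roger
corrections are out of scope; the containment approximation keeps the
type-I error of the group test near nominal (calibration is tested over
200 simulated null cohorts). Cohen's d uses the pooled-SD formula; the
Pearson p-value comes from the t transformation on n−2 df.

## Features and classifier

Each participant's vector is `[48 grid proportions, 20 AOI%, 20 durations,
20 dispersion indices]`, trial blocks ordered by trial index. Missing trial
values are imputed with the participant's own condition mean (falling back
to the participant mean), so imputation never crosses participants.
Standardization (z-score per dimension, variance floored at 10⁻⁸) and
augmentation (4 Gaussian-jitter copies per row, SD 0.05 in standardized
units) are fitted inside each training fold only; folds are stratified by
group. The network is 108 → 64 ReLU → 40 ReLU → 2 softmax with categorical
cross-entropy (the two-class reading of a binary cross-entropy objective),
trained with Adam (lr 0.01, per-step decay lr/(1+0.001·t), batch 2,
100 epochs by default) and inverted dropout (keep 0.5) on the hidden
activations. "Three-layer network … 64, 40, and 2" is read as two hidden
layers plus the 2-unit output; hidden activation and decay schedule are
choices the source architecture leaves open. The network is written on
numpy so runs are bit-reproducible from the seed; parameter count is
108·64+64 + 64·40+40 + 40·2+2 = 9,658. Classification tasks are
one-vs-control (depression vs control, mania vs control).

## Problem sizes and numerical choices

Tests and the acceptance script use: full 52-participant cohorts for
calibration/recovery checks; 200 trial-level null cohorts for mixed-model
type-I calibration (generated directly from the random-intercept model —
the property targets the fitting routine, not the gaze renderer); a
2000 × 2000 nearest-neighbour raster as the Voronoi oracle (per-cell
agreement within 10⁻³); 30-epoch training for the permutation-null
classifier check and 50 epochs for cohort classification, where the tested
property (chance level; beating the base rate) does not depend on training
length. Voronoi partition closure is asserted at 10⁻⁹ relative tolerance.

## Known limitations

- The dispersion index's absolute scale depends on fixations per trial;
  cross-study comparisons require matching detection parameters.
- Wald-F tests with containment df are approximate; small-sample df
  corrections are not implemented.
- The generator's quiz responses are independent of gaze, so joint
  gaze–performance analyses cannot be validated against it.
- Real-data inferential results (specific F/p values, correlations with
  symptom scales, published classification accuracies) require the original
  recordings and are outside what synthetic cohorts can certify.
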