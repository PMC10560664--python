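# gazeload

Eye-tracking analytics for attention allocation in simulated driving under
emotional issues (depression / mania / control) and cognitive load.

Drivers watching a first-person driving scene split their gaze between
safety-relevant regions — the front windshield, the rearview mirror and the
side mirror, modeled as rectangular areas of interest (AOIs) — and the rest
of the screen. `gazeload` quantifies that allocation from raw gaze streams
and tests how it shifts between emotional-state groups and between trials
with and without a concurrent arithmetic-quiz audio (high vs. no external
cognitive load). It is a library first (import it from Python), with an
`examples/` directory of narrative scripts and a thin `gazeload` CLI for
running the pipeline from a shell.

## What it computes

For gaze samples \((x_t, y_t)\) in the normalized unit square, recorded at
41 Hz over 20 trials of 30 s:

- **AOI sample percentage** — \(100 \cdot |\{t : (x_t,y_t) \in \text{AOI}\}| / n_{\text{valid}}\),
  the share of valid samples inside the AOI union.
- **AOI fixation duration** — total time in maximal runs of more than ten
  (≥ 11) consecutive in-AOI samples, i.e. sustained dwell, converted through
  the sampling rate.
- **Fixation-distribution index** — fixations are detected with the
  dispersion-threshold (I-DT) algorithm; the unit square is tessellated by
  the Voronoi diagram of the fixation centroids (cells clipped to the
  square) and the index is the median normalized cell area. Larger values
  mean more spatially dispersed gaze; the index drops when gaze concentrates
  on the road center under load ("visual centralization").
- **Group × load statistics** — participant-level condition means, group
  mean/SD summaries, pooled (load-collapsed) means, absolute and relative
  load-effect deltas, Cohen's *d*, Pearson correlations, and a linear mixed
  model (fixed effects: group, condition; random participant intercept;
  trials as repeated measures).
- **Classification** — a 108-dimensional per-participant vector (48 cell
  proportions of a 6 × 8 screen grid + 20 per-trial values of each of the
  three metrics) feeds a 108 → 64 → 40 → 2 softmax network (Adam, batch 2,
  lr 0.01 with 1/(1+0.001·t) decay, dropout keep 0.5, Gaussian-jitter
  augmentation) under stratified 10-fold cross-validation, classifying the
  depression or mania group against controls.

Because the original recordings are not public, the package ships a
synthetic cohort generator (`gazeload.synthetic`) that reproduces the study
design — 52 participants (19 control / 22 manic / 11 depression), 20 × 30 s
trials with alternating two-trial audio blocks, group × condition AOI-target
probabilities and dispersion levels, participant random effects, tracker
dropout, and per-group quiz accuracy — so every stage is testable end to
end.

## Worked example

```bash
python examples/load_effect_stats.py
```

prints (abridged):

```
                 metric      group  pooled_mean  absolute_change  percent_change
         aoi_sample_pct    control       68.030            5.060           7.725
         aoi_sample_pct depression       60.835            6.910          12.043
aoi_fixation_duration_s    control      404.700           31.000           7.965
  fixation_distribution depression        0.090           -0.014         -14.433

Mixed model on simulated trials (true condition effect +0.07):
  estimated effect magnitude 0.074, F(1, 985) = 418.4, p = 8.97e-78
```

The first block recomputes, from the bundled reference summary cells, the
load-collapsed pooled mean per group (e.g. control AOI% 68.03, depression
fixation distribution 0.090) and the load effects: AOI% rises by 5.06
percentage points for controls under load, durations rise by ~8%, and the
fixation-distribution index falls (gaze centralizes). The second block
fits the mixed model to a simulated trial table with a known +0.07
condition effect and recovers it with overwhelming evidence.

Other examples: `simulate_and_qc.py` (cohort simulation + gaze-capture QC),
`aoi_metrics_demo.py` (the two AOI metrics on one trial),
`fixation_dispersion_demo.py` (I-DT + Voronoi index under two dispersion
levels), `classify_groups.py` (feature building + cross-validated
classification). The same stages are available as CLI subcommands:
`gazeload simulate | qc | metrics | stats | features | classify | run |
replicate-table`.

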