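"""Depression-vs-control classification from 108-dimensional gaze features.

Simulates a reduced cohort (8 control, 6 depression participants), computes
per-trial AOI metrics and the fixation-distribution index, assembles each
participant's 108-vector (48 grid proportions + 3 x 20 trial metrics), and
runs stratified cross-validation of the 108 -> 64 -> 40 -> 2 softmax
network with in-fold standardization and Gaussian-jitter augmentation.
"""

import numpy as np

from gazeload import (
    ClassifierConfig,
    CohortConfig,
    TrialSchedule,
    build_feature_table,
    crossvalidate,
    default_aoi_set,
    feature_names,
    simulate_cohort,
)
from gazeload.pipeline import compute_cohort_metrics

schedule = TrialSchedule()
aoi = default_aoi_set()
cohort = simulate_cohort(
    CohortConfig(group_sizes={"control": 8, "depression": 6}, seed=5), schedule, aoi
)
metrics, _ = compute_cohort_metrics(cohort.recordings, aoi, schedule)
table = build_feature_table(cohort.recordings, metrics)

X = table[feature_names()].to_numpy()
y = table["group"].to_numpy()
res = crossvalidate(X, y, k=6, seed=0, config=ClassifierConfig(epochs=50, seed=0))

base = max(np.mean(y == "control"), np.mean(y == "depression"))
print(f"participants: {len(y)}  features per participant: {X.shape[1]}")
print(f"fold accuracies: {[round(a, 2) for a in res['fold_accuracies']]}")
print(f"mean CV accuracy: {res['mean_accuracy']:.2f}  (larger-class base rate {base:.2f})")
print(
    "\nAccuracy above the base rate shows the simulated group differences in "
    "AOI attention and gaze dispersion are recoverable from the feature vector."
)
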