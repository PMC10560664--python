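"""The 108-dimensional participant representation and its cross-validated
classification.

Layout (fixed, row-major): 48 grid-occupancy proportions over a 6 x 8
screen grid, then 20 per-trial AOI sample percentages, 20 per-trial AOI
fixation durations and 20 per-trial fixation-distribution indices
(48 + 3 x 20 = 108). Missing trial values are imputed with the
participant's own condition mean so no information crosses participants.

Cross-validation is stratified k-fold over participants; standardization
and augmentation are fitted inside each training fold only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .aoi import grid_occupancy
from .network import ClassifierConfig, DenseClassifier

N_GRID = 48
N_TRIALS = 20
N_FEATURES = N_GRID + 3 * N_TRIALS

TRIAL_METRIC_COLS = ("aoi_sample_pct", "aoi_fixation_duration_s", "fixation_distribution")


def feature_names(rows: int = 6, cols: int = 8, n_trials: int = N_TRIALS) -> list[str]:
    names = [f"g_r{r}_c{c}" for r in range(rows) for c in range(cols)]
    names += [f"aoi_pct_t{k}" for k in range(n_trials)]
    names += [f"aoi_dur_t{k}" for k in range(n_trials)]
    names += [f"fd_t{k}" for k in range(n_trials)]
    return names


def _impute_with_condition_mean(values: pd.Series, conditions: pd.Series) -> np.ndarray:
    v = values.to_numpy(dtype=float)
    if np.isnan(v).any():
        for cond in pd.unique(conditions):
            m = (conditions == cond).to_numpy()
            cell = v[m]
            if np.isnan(cell).any():
                fill = np.nanmean(cell) if np.isfinite(np.nanmean(cell)) else np.nanmean(v)
                cell[np.isnan(cell)] = fill if np.isfinite(fill) else 0.0
                v[m] = cell
    return v


def build_feature_vector(participant_metrics: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    """Assemble one participant's 108-vector from trial metrics + grid occupancy.

    *participant_metrics* must hold one row per trial (any order; rows are
    sorted by trial index). Missing metric values are imputed with the
    participant's own condition mean.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size != N_GRID:
        raise ValueError(f"grid occupancy must have {N_GRID} values, got {grid.size}")
    pm = participant_metrics.sort_values("trial")
    if len(pm) != N_TRIALS:
        raise ValueError(f"expected {N_TRIALS} trial rows, got {len(pm)}")
    blocks = [grid]
    for col in TRIAL_METRIC_COLS:
        blocks.append(_impute_with_condition_mean(pm[col], pm["condition"]))
    vec = np.concatenate(blocks)
    assert vec.size == N_FEATURES
    return vec


def build_feature_table(recordings, metrics: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per participant, 108 named columns
    plus ``participant_id`` and ``group``."""
    rows = []
    by_pid = {r.participant_id: r for r in recordings}
    for pid, pm in metrics.groupby("participant_id", sort=True):
        rec = by_pid[pid]
        m = rec.in_trial()
        grid = grid_occupancy(rec.x[m], rec.y[m], rec.valid[m])
        vec = build_feature_vector(pm, grid)
        row = dict(zip(feature_names(), vec))
        row["participant_id"] = pid
        row["group"] = pm["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def standardize_features(train: np.ndarray, eps: float = 1e-8):
    """Per-dimension z-scoring parameters from the training rows only.

    Returns ``((mean, sd), standardized_train)``; zero-variance dimensions
    get their SD floored at *eps* (the standardized column becomes 0)."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or len(train) < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    if np.any(sd < eps):
        import warnings

        warnings.warn("zero-variance feature dimension(s); variance floored", stacklevel=2)
    sd = np.maximum(sd, eps)
    return (mean, sd), (train - mean) / sd


def apply_standardization(params, X: np.ndarray) -> np.ndarray:
    mean, sd = params
    return (np.asarray(X, dtype=float) - mean) / sd


def augment_features(X, y, factor: int = 4, jitter_sd: float = 0.05, seed: int = 0):
    """Gaussian-jitter augmentation: *factor* noisy copies of every row are
    appended to the originals (jitter in standardized units)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if factor < 1:
        return X, y
    rng = np.random.default_rng(seed)
    copies = [X]
    labels = [y]
    for _ in range(factor):
        copies.append(X + rng.normal(0.0, jitter_sd, size=X.shape))
        labels.append(y)
    return np.concatenate(copies), np.concatenate(labels)


def train_classifier(X, y, config: ClassifierConfig | None = None) -> DenseClassifier:
    """Train the dense network on (already standardized) features."""
    X = np.asarray(X, dtype=float)
    clf = DenseClassifier(X.shape[1], config)
    clf.fit(X, y)
    return clf


def crossvalidate(
    X,
    y,
    k: int = 10,
    config: ClassifierConfig | None = None,
    augment_factor: int = 4,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV with in-fold standardization and augmentation.

    Returns ``{"fold_accuracies": [...], "mean_accuracy": float, "k": k}``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    config = ClassifierConfig() if config is None else config
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: a class is absent from the training split")
        params, Xtr = standardize_features(X[tr])
        Xte = apply_standardization(params, X[te])
        Xa, ya = augment_features(Xtr, y[tr], factor=augment_factor,
                                  jitter_sd=jitter_sd, seed=seed + fold)
        fold_cfg = ClassifierConfig(**{**config.__dict__, "seed": config.seed + fold})
        clf = train_classifier(Xa, ya, fold_cfg)
        accs.append(float(np.mean(clf.predict(Xte) == y[te])))
    return {"fold_accuracies": accs, "mean_accuracy": float(np.mean(accs)), "k": k}
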