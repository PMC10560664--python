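"""Areas of interest (AOI) and the sample-level attention metrics.

Three rectangular safety-relevant regions — front windshield, rearview
mirror, side mirror — define the AOI union. Two metrics quantify attention
to them:

* **AOI sample percentage** — percent of valid gaze samples inside the union;
* **AOI fixation duration** — total time spent in runs of more than ten
  consecutive in-AOI samples (>= 11 at 41 Hz, about 268 ms), i.e. dwell that
  is long enough to count as a fixation on the region.

A 6 x 8 grid occupancy over the whole screen provides the 48 spatial
dimensions of the downstream feature vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GazeRecording, TrialSchedule
from .errors import UndefinedMetricError

#: minimum run length for "more than ten consecutive" in-AOI samples
MIN_RUN_SAMPLES = 11


@dataclass(frozen=True)
class AOIRect:
    """Axis-aligned rectangle in normalized screen coordinates.

    Membership is half-open: ``[x0, x1) x [y0, y1)``, so tiled rectangles
    never double-count a point.
    """

    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 < self.x1 <= 1.0 and 0.0 <= self.y0 < self.y1 <= 1.0):
            raise ValueError(f"AOI {self.name!r} must satisfy 0<=x0<x1<=1, 0<=y0<y1<=1")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


class AOISet:
    """Ordered collection of named AOI rectangles (membership = union)."""

    def __init__(self, rects):
        self.rects = list(rects)
        names = [r.name for r in self.rects]
        if len(set(names)) != len(names):
            raise ValueError("AOI names must be unique")

    def __iter__(self):
        return iter(self.rects)

    def __len__(self) -> int:
        return len(self.rects)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rects]

    def contains(self, x, y) -> np.ndarray:
        """Boolean mask: inside any rectangle of the set."""
        x = np.asarray(x, dtype=float)
        mask = np.zeros(x.shape, dtype=bool)
        for r in self.rects:
            mask |= r.contains(x, y)
        return mask

    def to_json(self, path) -> str:
        payload = [
            {"name": r.name, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
            for r in self.rects
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return str(path)

    @classmethod
    def from_json(cls, path) -> "AOISet":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(AOIRect(**d) for d in payload)


def default_aoi_set() -> AOISet:
    """Default driving-scene AOIs (synthetic layout, config-overridable).

    The coordinates mimic a first-person dashboard view: a large central
    windshield, a rearview mirror at the top center and a side mirror at the
    left edge. They are fixtures for simulation and testing, not measured
    values.
    """
    return AOISet(
        [
            AOIRect("windshield", 0.15, 0.05, 0.85, 0.55),
            AOIRect("rearview_mirror", 0.40, 0.02, 0.60, 0.14),
            AOIRect("side_mirror", 0.02, 0.35, 0.14, 0.55),
        ]
    )


def point_in_aoi(x: float, y: float, aoi_set: AOISet):
    """Name of the first declared AOI containing (x, y), or ``None``."""
    for r in aoi_set:
        if bool(r.contains(x, y)):
            return r.name
    return None


def aoi_sample_percentage(x, y, valid, aoi_set: AOISet) -> float:
    """Percent of valid samples inside the AOI union."""
    valid = np.asarray(valid, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedMetricError("AOI sample percentage undefined: no valid samples")
    inside = aoi_set.contains(np.asarray(x)[valid], np.asarray(y)[valid])
    return 100.0 * float(inside.sum()) / n


def aoi_fixation_runs(in_aoi_flags, min_run: int = MIN_RUN_SAMPLES):
    """Maximal runs of consecutive True flags with length >= *min_run*.

    Returns ``[(start_index, length), ...]``. Invalid samples must already be
    encoded as False — tracker loss is not evidence of dwell and breaks runs.
    """
    f = np.asarray(in_aoi_flags, dtype=bool)
    if f.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], f, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    keep = lengths >= min_run
    return list(zip(starts[keep].tolist(), lengths[keep].tolist()))


def aoi_fixation_duration(
    x, y, valid, aoi_set: AOISet, sampling_rate_hz: float, min_run: int = MIN_RUN_SAMPLES
) -> float:
    """Total time (s) in qualifying in-AOI runs: qualifying samples / rate."""
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    flags = aoi_set.contains(x, y) & np.asarray(valid, dtype=bool)
    total = sum(length for _, length in aoi_fixation_runs(flags, min_run=min_run))
    return total / sampling_rate_hz


def grid_occupancy(x, y, valid=None, rows: int = 6, cols: int = 8) -> np.ndarray:
    """Row-major proportions of valid samples per cell of a rows x cols grid.

    Cell of a sample: ``r = min(floor(y*rows), rows-1)``,
    ``c = min(floor(x*cols), cols-1)`` (the closing screen edge folds into
    the last cell). Proportions sum to 1 over valid samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    valid = np.asarray(valid, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedMetricError("grid occupancy undefined: no valid samples")
    r = np.minimum((y[valid] * rows).astype(int), rows - 1)
    c = np.minimum((x[valid] * cols).astype(int), cols - 1)
    counts = np.zeros((rows, cols), dtype=float)
    np.add.at(counts, (r, c), 1.0)
    return (counts / n).ravel()


def compute_trial_metrics(
    recording: GazeRecording,
    aoi_set: AOISet,
    schedule: TrialSchedule,
    min_run: int = MIN_RUN_SAMPLES,
) -> pd.DataFrame:
    """Per-trial AOI metrics for one segmented recording.

    Returns one row per trial with ``aoi_sample_pct``, ``aoi_fixation_duration_s``
    and ``n_valid_samples``; the ``fixation_distribution`` column is created
    empty and filled by the dispersion stage. Trials whose samples are all
    invalid are emitted with missing metrics and a warning.
    """
    rows = []
    for k in range(schedule.n_trials):
        t, x, y, valid = recording.trial_slice(k)
        n_valid = int(np.asarray(valid, bool).sum())
        if n_valid == 0:
            warnings.warn(
                f"participant {recording.participant_id!r} trial {k}: no valid "
                "samples; metrics missing",
                stacklevel=2,
            )
            pct = np.nan
            dur = np.nan
        else:
            pct = aoi_sample_percentage(x, y, valid, aoi_set)
            dur = aoi_fixation_duration(
                x, y, valid, aoi_set, recording.sampling_rate_hz, min_run=min_run
            )
        rows.append(
            {
                "participant_id": recording.participant_id,
                "group": recording.group,
                "trial": k,
                "condition": schedule.condition_of(k),
                "aoi_sample_pct": pct,
                "aoi_fixation_duration_s": dur,
                "fixation_distribution": np.nan,
                "n_valid_samples": n_valid,
            }
        )
    return pd.DataFrame(rows)
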