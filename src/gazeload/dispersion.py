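"""Fixation detection and the Voronoi fixation-distribution index.

Gaze concentration ("visual centralization") is quantified by tessellating
the unit square with the Voronoi diagram of a trial's fixation centroids and
taking the median normalized cell area. Tightly clustered fixations produce
many tiny cells, so the index shrinks as gaze concentrates; it lies in
(0, 1] and is larger the more dispersed attention is.

Fixations are detected with the standard dispersion-threshold (I-DT)
algorithm: a time window grows while its spatial extent
(max x − min x) + (max y − min y) stays under a threshold, and is emitted as
a fixation once it spans a minimum duration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from .errors import DegenerateGeometryError

UNIT_SQUARE = (0.0, 0.0, 1.0, 1.0)


@dataclass(frozen=True)
class Fixation:
    x: float
    y: float
    onset_s: float
    offset_s: float
    n_samples: int


def detect_fixations_idt(
    t,
    x,
    y,
    valid=None,
    dispersion_threshold: float = 0.03,
    min_duration_s: float = 0.1,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection on one trial's samples.

    Parameters are in normalized screen units and seconds; the defaults
    (0.03 ≈ the tracker's 1.25° accuracy, 100 ms) are conventional. Invalid
    samples break windows — a fixation never bridges tracker loss.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    valid = np.asarray(valid, dtype=bool)

    fixations: list[Fixation] = []
    n = len(t)
    seg_start = 0
    while seg_start < n:
        if not valid[seg_start]:
            seg_start += 1
            continue
        seg_end = seg_start
        while seg_end < n and valid[seg_end]:
            seg_end += 1
        fixations.extend(
            _idt_segment(
                t[seg_start:seg_end],
                x[seg_start:seg_end],
                y[seg_start:seg_end],
                dispersion_threshold,
                min_duration_s,
            )
        )
        seg_start = seg_end
    return fixations


def _idt_segment(t, x, y, threshold, min_duration_s):
    out = []
    n = len(t)
    i = 0
    while i < n:
        # smallest window starting at i that spans min_duration_s
        j = i
        while j < n and t[j] - t[i] < min_duration_s:
            j += 1
        if j >= n:
            break
        lo_x, hi_x = x[i : j + 1].min(), x[i : j + 1].max()
        lo_y, hi_y = y[i : j + 1].min(), y[i : j + 1].max()
        if (hi_x - lo_x) + (hi_y - lo_y) > threshold:
            i += 1
            continue
        # grow while dispersion holds
        while j + 1 < n:
            nx, ny = x[j + 1], y[j + 1]
            d = (max(hi_x, nx) - min(lo_x, nx)) + (max(hi_y, ny) - min(lo_y, ny))
            if d > threshold:
                break
            j += 1
            lo_x, hi_x = min(lo_x, nx), max(hi_x, nx)
            lo_y, hi_y = min(lo_y, ny), max(hi_y, ny)
        out.append(
            Fixation(
                x=float(x[i : j + 1].mean()),
                y=float(y[i : j + 1].mean()),
                onset_s=float(t[i]),
                offset_s=float(t[j]),
                n_samples=j - i + 1,
            )
        )
        i = j + 1
    return out


def _convex_polygon_area(verts: np.ndarray) -> float:
    """Shoelace area of a convex polygon given in any vertex order."""
    c = verts.mean(axis=0)
    ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
    v = verts[np.argsort(ang)]
    xs, ys = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))


def voronoi_cell_areas(points, bounds=UNIT_SQUARE) -> np.ndarray:
    """Area of each point's Voronoi cell clipped to a rectangular bound.

    Clipping uses mirrored-point augmentation: every point is reflected
    across the four sides of the bounding rectangle, so each original cell is
    finite and coincides exactly with the clipped cell. Exactly coincident
    points are perturbed by a deterministic 1e-9 jitter so the tessellation
    is defined; the areas partition the rectangle (they sum to its area).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points for a tessellation")
    # perturb exact duplicates with a seeded jitter
    _, first_idx = np.unique(pts, axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(n), first_idx)
    if len(dup):
        rng = np.random.default_rng(851201)
        pts = pts.copy()
        pts[dup] += rng.normal(scale=1e-9, size=(len(dup), 2))
    if len(np.unique(np.round(pts, 12), axis=0)) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct points")

    x0, y0, x1, y1 = bounds
    X, Y = pts[:, 0], pts[:, 1]
    mirrored = np.concatenate(
        [
            pts,
            np.column_stack([2 * x0 - X, Y]),
            np.column_stack([2 * x1 - X, Y]),
            np.column_stack([X, 2 * y0 - Y]),
            np.column_stack([X, 2 * y1 - Y]),
        ]
    )
    vor = Voronoi(mirrored)
    areas = np.empty(n, dtype=float)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # cannot happen for interior points
            raise DegenerateGeometryError(f"unbounded cell for point {i}")
        areas[i] = _convex_polygon_area(vor.vertices[region])
    return areas


def fixation_distribution(fixations, bounds=UNIT_SQUARE) -> float:
    """Median normalized Voronoi cell area of fixation centroids.

    Returns NaN (missing) for fewer than 3 fixations or degenerate geometry.
    Larger values mean more spatially dispersed gaze.
    """
    if len(fixations) < 3:
        return math.nan
    pts = np.array(
        [(f.x, f.y) if isinstance(f, Fixation) else tuple(f) for f in fixations],
        dtype=float,
    )
    try:
        areas = voronoi_cell_areas(pts, bounds=bounds)
    except DegenerateGeometryError as exc:
        warnings.warn(f"fixation distribution missing: {exc}", stacklevel=2)
        return math.nan
    x0, y0, x1, y1 = bounds
    return float(np.median(areas) / ((x1 - x0) * (y1 - y0)))


def add_fixation_distribution(
    metrics: pd.DataFrame,
    recording,
    schedule,
    dispersion_threshold: float = 0.03,
    min_duration_s: float = 0.1,
) -> pd.DataFrame:
    """Fill the ``fixation_distribution`` column of one participant's metrics."""
    metrics = metrics.copy()
    for k in range(schedule.n_trials):
        t, x, y, valid = recording.trial_slice(k)
        fx = detect_fixations_idt(
            t, x, y, valid,
            dispersion_threshold=dispersion_threshold,
            min_duration_s=min_duration_s,
        )
        fd = fixation_distribution(fx)
        sel = (metrics["participant_id"] == recording.participant_id) & (
            metrics["trial"] == k
        )
        metrics.loc[sel, "fixation_distribution"] = fd
    return metrics


def condition_dispersion(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean fixation-distribution index per participant x condition.

    Unweighted mean over non-missing trials; a participant x condition cell
    with no usable trial is reported missing with a warning.
    """
    out = (
        metrics.groupby(["participant_id", "group", "condition"], sort=True)[
            "fixation_distribution"
        ]
        .mean()
        .reset_index()
    )
    n_missing = int(out["fixation_distribution"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} participant x condition cell(s) have no usable trials",
            stacklevel=2,
        )
    return out
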