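"""Gaze data model, CSV I/O, trial segmentation and quality control.

All analysis coordinates live in the normalized unit square: origin at the
top-left of the screen, ``x`` rightward, ``y`` downward, both in ``[0, 1]``.
Samples the tracker failed to capture carry ``valid = False`` and NaN
coordinates; they count only toward the gaze-capture fraction, never toward
any metric denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UndefinedMetricError

NO_LOAD = "no_load"
HIGH_LOAD = "high_load"

#: canonical gaze-table column order
GAZE_COLUMNS = ["participant_id", "group", "trial", "t", "x", "y", "valid"]

GROUPS = ("control", "manic", "depression")


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical pixel geometry of the display; analysis itself is resolution-free."""

    width_px: int = 1920
    height_px: int = 1080

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")


def _default_conditions(n_trials: int) -> tuple[str, ...]:
    # alternating blocks of two: two audio (high load) trials, two silent, repeating
    pattern = (HIGH_LOAD, HIGH_LOAD, NO_LOAD, NO_LOAD)
    return tuple(pattern[i % 4] for i in range(n_trials))


@dataclass(frozen=True)
class TrialSchedule:
    """Timing and cognitive-load condition of each trial.

    The default reproduces the experimental paradigm: 20 clips of 30 s
    separated by 2 s gaps, with audio (arithmetic-quiz) trials and silent
    trials alternating in blocks of two, so each condition covers exactly
    half the trials.
    """

    n_trials: int = 20
    trial_duration_s: float = 30.0
    inter_trial_gap_s: float = 2.0
    conditions: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.conditions is None:
            object.__setattr__(self, "conditions", _default_conditions(self.n_trials))
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(self.conditions) != self.n_trials:
            raise ValueError("conditions must label every trial")
        bad = set(self.conditions) - {NO_LOAD, HIGH_LOAD}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def period_s(self) -> float:
        return self.trial_duration_s + self.inter_trial_gap_s

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * self.period_s - self.inter_trial_gap_s

    def trial_start(self, k: int) -> float:
        return k * self.period_s

    def condition_of(self, k: int) -> str:
        return self.conditions[k]

    def trial_of_time(self, t: np.ndarray) -> np.ndarray:
        """Trial index for each time (−1 for gaps / out of schedule).

        Sample at time t belongs to trial k iff
        ``k*(dur+gap) <= t < k*(dur+gap) + dur`` (half-open windows).
        """
        t = np.asarray(t, dtype=float)
        k = np.floor(t / self.period_s).astype(int)
        within = t - k * self.period_s
        in_window = (within < self.trial_duration_s) & (k >= 0) & (k < self.n_trials)
        return np.where(in_window, k, -1)

    def high_load_trials(self) -> list[int]:
        return [k for k, c in enumerate(self.conditions) if c == HIGH_LOAD]

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "trial_duration_s": self.trial_duration_s,
            "inter_trial_gap_s": self.inter_trial_gap_s,
            "conditions": list(self.conditions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchedule":
        cond = d.get("conditions")
        return cls(
            n_trials=int(d.get("n_trials", 20)),
            trial_duration_s=float(d.get("trial_duration_s", 30.0)),
            inter_trial_gap_s=float(d.get("inter_trial_gap_s", 2.0)),
            conditions=tuple(cond) if cond is not None else None,
        )


@dataclass
class GazeRecording:
    """One participant's timestamped gaze stream.

    Arrays are parallel and sorted by ``t``. ``trial`` holds the per-sample
    trial index (−1 for inter-trial gaps or before segmentation).
    """

    participant_id: str
    group: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    trial: np.ndarray = None  # type: ignore[assignment]
    sampling_rate_hz: float = 41.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.trial is None:
            self.trial = np.full(self.t.shape, -1, dtype=int)
        self.trial = np.asarray(self.trial, dtype=int)
        n = len(self.t)
        if not all(len(a) == n for a in (self.x, self.y, self.valid, self.trial)):
            raise ValueError("sample arrays must have equal length")
        if n and np.any(np.diff(self.t) < 0):
            raise DataError(f"timestamps not non-decreasing for {self.participant_id!r}")

    def __len__(self) -> int:
        return len(self.t)

    def in_trial(self) -> np.ndarray:
        """Boolean mask of samples inside any trial window."""
        return self.trial >= 0

    def trial_slice(self, k: int):
        m = self.trial == k
        return self.t[m], self.x[m], self.y[m], self.valid[m]


@dataclass(frozen=True)
class QCReport:
    participant_id: str
    gaze_capture_fraction: float
    excluded: bool
    threshold: float = 0.25


def read_gaze_table(path) -> list[GazeRecording]:
    """Read the canonical gaze CSV into one :class:`GazeRecording` per participant.

    Required header: ``participant_id,group,trial,t,x,y,valid``. Rows with an
    unparseable ``t`` or ``valid`` field are a format error (reported, never
    silently dropped); non-monotone timestamps within a participant raise
    :class:`DataError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze table {path} missing column(s): {', '.join(missing)}")
    for col in ("t", "x", "y", "valid", "trial"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_rows = df.index[df["t"].isna() | df["valid"].isna() | df["trial"].isna()]
    if len(bad_rows):
        raise FormatError(
            f"gaze table {path}: {len(bad_rows)} malformed row(s), first at line "
            f"{int(bad_rows[0]) + 2}"
        )
    recordings = []
    for pid, sub in df.groupby("participant_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise DataError(f"participant {pid!r} appears with multiple group labels")
        recordings.append(
            GazeRecording(
                participant_id=str(pid),
                group=str(groups[0]),
                t=sub["t"].to_numpy(),
                x=sub["x"].to_numpy(),
                y=sub["y"].to_numpy(),
                valid=sub["valid"].to_numpy().astype(bool),
                trial=sub["trial"].to_numpy().astype(int),
            )
        )
    return recordings


def write_gaze_table(recordings, path) -> str:
    """Write recordings to the canonical CSV dialect; re-readable losslessly.

    Coordinates are printed with 9 decimal places (round trips exceed the
    6-decimal contract); invalid samples keep empty coordinate fields.
    """
    recs = list(recordings)
    if not recs:
        raise ValueError("cannot write an empty collection of recordings")
    frames = []
    for r in recs:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": r.participant_id,
                    "group": r.group,
                    "trial": r.trial,
                    "t": r.t,
                    "x": r.x,
                    "y": r.y,
                    "valid": r.valid.astype(int),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)[GAZE_COLUMNS]
    out.to_csv(path, index=False, float_format="%.9f")
    return str(path)


def segment_trials(recording: GazeRecording, schedule: TrialSchedule) -> GazeRecording:
    """Return a copy of *recording* with per-sample trial labels from *schedule*.

    Gap samples (between trials, or beyond the schedule) get trial −1. A
    recording that does not span the full schedule is labeled as far as it
    goes, with a warning.
    """
    trial = schedule.trial_of_time(recording.t)
    if len(recording) and recording.t[-1] < schedule.total_duration_s - schedule.inter_trial_gap_s:
        warnings.warn(
            f"recording {recording.participant_id!r} ends at t={recording.t[-1]:.1f}s, "
            f"before the schedule span of {schedule.total_duration_s:.0f}s; "
            "later trials will have no samples",
            stacklevel=2,
        )
    return replace(recording, trial=trial)


def qc_gaze_capture(recording: GazeRecording, threshold: float = 0.25) -> QCReport:
    """Gaze-capture QC: fraction of in-trial samples the tracker captured.

    Participants are excluded when the fraction is strictly below *threshold*
    (default 25%); gap samples do not count as stimulus time.
    """
    m = recording.in_trial()
    n = int(m.sum())
    if n == 0:
        raise UndefinedMetricError(
            f"participant {recording.participant_id!r} has no in-trial samples; "
            "gaze-capture fraction undefined"
        )
    frac = float(recording.valid[m].sum()) / n
    return QCReport(
        participant_id=recording.participant_id,
        gaze_capture_fraction=frac,
        excluded=frac < threshold,
        threshold=threshold,
    )
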