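"""Synthetic gaze cohorts with the structure the analysis assumes.

The generator emulates the study conditions the downstream stages are built
for: 52 participants (19 control / 22 manic / 11 depression), 20 trials of
30 s sampled at 41 Hz, two cognitive-load conditions, group x condition
targets for the probability that a fixation lands in the AOI union,
condition-dependent spatial spread of background (non-AOI) fixations,
participant-level random effects, tracker dropout, and per-group arithmetic
quiz accuracy.

Effects are encoded at the fixation level: each fixation's target is either
an AOI (chosen by per-AOI weights, uniform inside the rectangle) or a
background location drawn from a center Gaussian constrained to lie outside
the AOI union. Dwell structure (alternating lognormal fixations and short
saccades) makes run-length-based duration metrics behave realistically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aoi import AOISet, default_aoi_set
from .core import HIGH_LOAD, NO_LOAD, GROUPS, GazeRecording, TrialSchedule
from .errors import ConfigError

#: default probability that an AOI-directed fixation targets each region
DEFAULT_AOI_WEIGHTS = {"windshield": 0.80, "rearview_mirror": 0.10, "side_mirror": 0.10}

# group x condition targets for AOI sample probability (no_load, high_load)
_DEFAULT_P_AOI = {
    ("control", NO_LOAD): 0.6550,
    ("control", HIGH_LOAD): 0.7056,
    ("manic", NO_LOAD): 0.6586,
    ("manic", HIGH_LOAD): 0.7338,
    ("depression", NO_LOAD): 0.5738,
    ("depression", HIGH_LOAD): 0.6429,
}

# spatial SD of the background-fixation Gaussian; smaller under load
# ("visual centralization") and ordered across groups like the FD findings
_DEFAULT_DISPERSION = {
    ("control", NO_LOAD): 0.24,
    ("control", HIGH_LOAD): 0.17,
    ("manic", NO_LOAD): 0.23,
    ("manic", HIGH_LOAD): 0.15,
    ("depression", NO_LOAD): 0.20,
    ("depression", HIGH_LOAD): 0.13,
}

_DEFAULT_QUIZ = {"control": 0.6386, "manic": 0.5848, "depression": 0.5455}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    group_sizes: dict = field(
        default_factory=lambda: {"control": 19, "manic": 22, "depression": 11}
    )
    p_aoi: dict = field(default_factory=lambda: dict(_DEFAULT_P_AOI))
    dispersion_scale: dict = field(default_factory=lambda: dict(_DEFAULT_DISPERSION))
    between_participant_sd: float = 0.10
    validity_rate: float = 0.9
    quiz_accuracy: dict = field(default_factory=lambda: dict(_DEFAULT_QUIZ))
    fixation_duration_mean_s: float = 0.30
    fixation_duration_sigma: float = 0.4  # lognormal shape
    saccade_duration_s: float = 0.04
    jitter_sd: float = 0.005
    aoi_weights: dict = field(default_factory=lambda: dict(DEFAULT_AOI_WEIGHTS))
    questions_per_quiz_trial: int = 3
    center_offsets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigError(f"group size for {g!r} must be >= 1")
        for k, p in self.p_aoi.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"p_aoi{k} outside [0, 1]")
        for k, s in self.dispersion_scale.items():
            if s <= 0:
                raise ConfigError(f"dispersion_scale{k} must be > 0")
        if abs(sum(self.aoi_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("aoi_weights must sum to 1")
        if not 0.0 <= self.validity_rate <= 1.0:
            raise ConfigError("validity_rate outside [0, 1]")


@dataclass
class Cohort:
    recordings: list
    roster: pd.DataFrame
    quiz: pd.DataFrame
    config: CohortConfig


def _draw_background_center(rng, dispersion_scale, aoi_set, max_tries: int = 200):
    """Center Gaussian at (0.5, 0.5), inside the unit square and outside the AOI
    union; falls back to the last in-square draw if rejection keeps failing
    (e.g. a vanishing scale with the screen center covered by an AOI)."""
    last = (0.5, 0.5)
    for _ in range(max_tries):
        cx, cy = rng.normal(0.5, dispersion_scale, size=2)
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            continue
        last = (cx, cy)
        if not bool(aoi_set.contains(cx, cy)):
            return last
    return last


def simulate_fixation_sequence(
    trial_duration_s: float,
    p_aoi_effective: float,
    dispersion_scale: float,
    aoi_set: AOISet,
    rng: np.random.Generator,
    weights: dict | None = None,
    fixation_duration_mean_s: float = 0.30,
    fixation_duration_sigma: float = 0.4,
    saccade_duration_s: float = 0.04,
) -> list[tuple[float, float, float, float]]:
    """Alternating fixations/saccades filling one trial.

    Returns ``[(cx, cy, onset_s, offset_s), ...]``. Each fixation targets the
    AOI union with probability *p_aoi_effective* (a weighted AOI chosen, the
    center uniform inside it); otherwise a background location from a center
    Gaussian with SD *dispersion_scale* kept outside the union.
    """
    if not 0.0 <= p_aoi_effective <= 1.0:
        raise ConfigError("p_aoi_effective outside [0, 1]")
    if p_aoi_effective > 0 and len(aoi_set) == 0:
        raise ConfigError("AOI-directed fixations requested but the AOI set is empty")
    weights = dict(DEFAULT_AOI_WEIGHTS) if weights is None else weights
    names = list(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    rect_of = {r.name: r for r in aoi_set}
    unknown = [n for n in names if n not in rect_of]
    if unknown and p_aoi_effective > 0:
        raise ConfigError(f"aoi_weights reference unknown AOI(s): {unknown}")

    mu = np.log(fixation_duration_mean_s) - 0.5 * fixation_duration_sigma**2
    seq = []
    t = 0.0
    while t < trial_duration_s:
        dur = float(rng.lognormal(mu, fixation_duration_sigma))
        offset = min(t + dur, trial_duration_s)
        if rng.random() < p_aoi_effective:
            r = rect_of[names[rng.choice(len(names), p=w)]]
            cx = rng.uniform(r.x0, r.x1)
            cy = rng.uniform(r.y0, r.y1)
        else:
            cx, cy = _draw_background_center(rng, dispersion_scale, aoi_set)
        seq.append((float(cx), float(cy), t, offset))
        t = offset + saccade_duration_s
    return seq


def render_samples(
    fixations,
    rng: np.random.Generator,
    sampling_rate_hz: float = 41.0,
    trial_duration_s: float = 30.0,
    jitter_sd: float = 0.005,
    validity_rate: float = 0.9,
):
    """Sample the fixation sequence at the tracker rate.

    In-fixation samples are the centroid plus isotropic Gaussian jitter;
    saccade samples interpolate linearly between the surrounding centroids.
    Each sample is captured with probability *validity_rate*; missed samples
    get NaN coordinates. Returns ``(t, x, y, valid)`` with t relative to
    trial onset.
    """
    if not fixations:
        raise ValueError("fixation sequence is empty")
    n = int(round(trial_duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    cx = np.array([f[0] for f in fixations])
    cy = np.array([f[1] for f in fixations])
    onsets = np.array([f[2] for f in fixations])
    offsets = np.array([f[3] for f in fixations])

    # index of the last fixation with onset <= t (clipped to a valid range)
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 1)
    x = cx[idx].copy()
    y = cy[idx].copy()
    in_sacc = (t > offsets[idx]) & (idx < len(onsets) - 1)
    if np.any(in_sacc):
        i = idx[in_sacc]
        frac = (t[in_sacc] - offsets[i]) / np.maximum(onsets[i + 1] - offsets[i], 1e-12)
        x[in_sacc] = cx[i] + frac * (cx[i + 1] - cx[i])
        y[in_sacc] = cy[i] + frac * (cy[i + 1] - cy[i])
    if jitter_sd > 0:
        in_fix = ~in_sacc
        x[in_fix] += rng.normal(0.0, jitter_sd, size=int(in_fix.sum()))
        y[in_fix] += rng.normal(0.0, jitter_sd, size=int(in_fix.sum()))
    np.clip(x, 0.0, 1.0, out=x)
    np.clip(y, 0.0, 1.0, out=y)
    valid = rng.random(n) < validity_rate
    x[~valid] = np.nan
    y[~valid] = np.nan
    return t, x, y, valid


def simulate_participant(
    participant_id: str,
    group: str,
    config: CohortConfig,
    schedule: TrialSchedule,
    aoi_set: AOISet,
    rng: np.random.Generator,
    p_offset: float | None = None,
):
    """One participant's recording plus quiz answers.

    The participant's random effect is an additive offset on the AOI target
    probability, shared across trials and conditions and clamped to [0, 1].
    Quiz answers exist only for high-load trials (3 Bernoulli answers each).
    """
    if group not in config.group_sizes:
        raise ConfigError(f"unknown group {group!r}")
    if p_offset is None:
        p_offset = float(rng.normal(0.0, config.between_participant_sd))
    ts, xs, ys, vs, trials = [], [], [], [], []
    quiz_rows = []
    for k in range(schedule.n_trials):
        cond = schedule.condition_of(k)
        p_eff = float(np.clip(config.p_aoi[(group, cond)] + p_offset, 0.0, 1.0))
        seq = simulate_fixation_sequence(
            schedule.trial_duration_s,
            p_eff,
            config.dispersion_scale[(group, cond)],
            aoi_set,
            rng,
            weights=config.aoi_weights,
            fixation_duration_mean_s=config.fixation_duration_mean_s,
            fixation_duration_sigma=config.fixation_duration_sigma,
            saccade_duration_s=config.saccade_duration_s,
        )
        t, x, y, valid = render_samples(
            seq,
            rng,
            sampling_rate_hz=41.0,
            trial_duration_s=schedule.trial_duration_s,
            jitter_sd=config.jitter_sd,
            validity_rate=config.validity_rate,
        )
        ts.append(t + schedule.trial_start(k))
        xs.append(x)
        ys.append(y)
        vs.append(valid)
        trials.append(np.full(len(t), k, dtype=int))
        if cond == HIGH_LOAD:
            acc = config.quiz_accuracy[group]
            for q in range(config.questions_per_quiz_trial):
                quiz_rows.append(
                    {
                        "participant_id": participant_id,
                        "group": group,
                        "trial": k,
                        "question": q,
                        "correct": int(rng.random() < acc),
                    }
                )
    rec = GazeRecording(
        participant_id=participant_id,
        group=group,
        t=np.concatenate(ts),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        valid=np.concatenate(vs),
        trial=np.concatenate(trials),
        sampling_rate_hz=41.0,
    )
    return rec, pd.DataFrame(quiz_rows)


def simulate_cohort(
    config: CohortConfig | None = None,
    schedule: TrialSchedule | None = None,
    aoi_set: AOISet | None = None,
) -> Cohort:
    """Full cohort honoring the configured group sizes; deterministic per seed.

    Participant offsets are drawn N(0, between_participant_sd) and, by
    default, centered within each group so the configured group-level AOI
    probabilities are the actual cohort-level targets while the
    between-participant spread is preserved.
    """
    config = CohortConfig() if config is None else config
    schedule = TrialSchedule() if schedule is None else schedule
    aoi_set = default_aoi_set() if aoi_set is None else aoi_set

    prefix = {"control": "c", "manic": "m", "depression": "d"}
    ss = np.random.SeedSequence(config.seed)
    offset_rng = np.random.default_rng(ss.spawn(1)[0])
    recordings, quiz_frames, roster_rows = [], [], []
    for group in GROUPS:
        if group not in config.group_sizes:
            continue
        n = config.group_sizes[group]
        offsets = offset_rng.normal(0.0, config.between_participant_sd, size=n)
        if config.center_offsets and n > 1:
            offsets -= offsets.mean()
        for i in range(n):
            pid = f"{prefix.get(group, group[0])}{i + 1:02d}"
            group_key = zlib.crc32(group.encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, group_key, i])
            )
            rec, quiz = simulate_participant(
                pid, group, config, schedule, aoi_set, rng, p_offset=float(offsets[i])
            )
            recordings.append(rec)
            quiz_frames.append(quiz)
            roster_rows.append({"participant_id": pid, "group": group})
    return Cohort(
        recordings=recordings,
        roster=pd.DataFrame(roster_rows),
        quiz=pd.concat(quiz_frames, ignore_index=True),
        config=config,
    )


def simulate_trial_metrics_table(
    n_per_group: dict | None = None,
    n_trials: int = 20,
    grand_mean: float = 0.65,
    group_effects: dict | None = None,
    condition_effect: float = 0.0,
    participant_sd: float = 0.08,
    trial_sd: float = 0.06,
    seed: int = 0,
    metric: str = "aoi_proportion",
) -> pd.DataFrame:
    """Trial-level metric table from a Gaussian random-intercept model.

    A lightweight generator for exercising the mixed-model stage directly
    (null calibration, power, estimate recovery) without rendering gaze
    streams: response = grand mean + group effect + condition effect +
    participant intercept + trial noise, with the default block-of-two
    condition layout.
    """
    n_per_group = {"control": 19, "manic": 22, "depression": 11} if n_per_group is None else n_per_group
    group_effects = {} if group_effects is None else group_effects
    rng = np.random.default_rng(seed)
    sched = TrialSchedule(n_trials=n_trials)
    rows = []
    pid_counter = 0
    for group, n in n_per_group.items():
        for _ in range(n):
            pid = f"p{pid_counter:03d}"
            pid_counter += 1
            intercept = rng.normal(0.0, participant_sd)
            for k in range(n_trials):
                cond = sched.condition_of(k)
                val = (
                    grand_mean
                    + group_effects.get(group, 0.0)
                    + (condition_effect if cond == HIGH_LOAD else 0.0)
                    + intercept
                    + rng.normal(0.0, trial_sd)
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "trial": k,
                        "condition": cond,
                        metric: val,
                    }
                )
    return pd.DataFrame(rows)
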