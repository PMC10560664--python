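"""Group x cognitive-load statistics for the gaze metrics.

Summaries follow the repeated-measures layout of the study: each
participant's trials are first averaged within a condition, and group means
and SDs are taken over those participant-level condition means. Load effects
come in two conventions, matching how such results are usually reported:
absolute change (percentage-point / index-unit difference between high load
and no load) and relative change (percent of the no-load value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .core import HIGH_LOAD, NO_LOAD
from .errors import UndefinedMetricError

METRICS = ("aoi_sample_pct", "aoi_fixation_duration_s", "fixation_distribution")


def condition_summary(metrics: pd.DataFrame, metric_cols=METRICS) -> pd.DataFrame:
    """Mean/SD/n per (group, condition, metric), over participant condition-means.

    SD uses the n−1 denominator; a single-participant cell reports SD 0 with
    a degeneracy warning.
    """
    present = [c for c in metric_cols if c in metrics.columns]
    per_part = (
        metrics.groupby(["participant_id", "group", "condition"], sort=True)[present]
        .mean()
        .reset_index()
    )
    rows = []
    for (group, cond), sub in per_part.groupby(["group", "condition"], sort=True):
        for metric in present:
            vals = sub[metric].dropna().to_numpy()
            if len(vals) == 0:
                warnings.warn(f"empty cell ({group}, {cond}, {metric})", stacklevel=2)
                continue
            if len(vals) == 1:
                warnings.warn(
                    f"single participant in cell ({group}, {cond}, {metric}); SD "
                    "degenerate, reported as 0",
                    stacklevel=2,
                )
                sd = 0.0
            else:
                sd = float(np.std(vals, ddof=1))
            rows.append(
                {
                    "group": group,
                    "condition": cond,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "sd": sd,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def _cell_mean(summary: pd.DataFrame, metric: str, group: str, condition: str) -> float:
    sel = summary[
        (summary["metric"] == metric)
        & (summary["group"] == group)
        & (summary["condition"] == condition)
    ]
    if len(sel) != 1:
        raise UndefinedMetricError(
            f"summary has no unique entry for ({group}, {condition}, {metric})"
        )
    return float(sel["mean"].iloc[0])


def pooled_group_mean(summary: pd.DataFrame, metric: str, group: str) -> float:
    """Load-collapsed group mean: equal-weight average of the two condition
    means (both conditions cover the same number of trials)."""
    lo = _cell_mean(summary, metric, group, NO_LOAD)
    hi = _cell_mean(summary, metric, group, HIGH_LOAD)
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class EffectReport:
    metric: str
    group: str
    no_load_mean: float
    high_load_mean: float
    absolute_change: float
    percent_change: float
    pooled_mean: float


def load_effect(summary: pd.DataFrame, metric: str, group: str) -> EffectReport:
    """High-load minus no-load effect for one group, in both conventions."""
    lo = _cell_mean(summary, metric, group, NO_LOAD)
    hi = _cell_mean(summary, metric, group, HIGH_LOAD)
    if lo == 0:
        raise ZeroDivisionError("relative change undefined: no-load mean is 0")
    return EffectReport(
        metric=metric,
        group=group,
        no_load_mean=lo,
        high_load_mean=hi,
        absolute_change=hi - lo,
        percent_change=100.0 * (hi - lo) / lo,
        pooled_mean=0.5 * (lo + hi),
    )


def cohens_d(values_a, values_b) -> float:
    """Standardized mean difference with the pooled SD.

    d = (mean_a − mean_b) / s_p,
    s_p² = ((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    sp = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    if sp == 0:
        raise UndefinedMetricError("pooled SD is zero; Cohen's d undefined")
    return float((a.mean() - b.mean()) / sp)


def pearson_correlation(x, y):
    """Product-moment r with the two-tailed p from the t approximation,
    t = r sqrt((n−2)/(1−r²)) on n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("correlation undefined for constant input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a given r and sample size (for published-r checks)."""
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))


@dataclass
class MixedModelEffect:
    effect: str
    f_stat: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class MixedModelResult:
    effects: list
    fixed_effects: pd.DataFrame
    converged: bool
    model: object

    def effect(self, name: str) -> MixedModelEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)


def fit_mixed_model(
    metrics: pd.DataFrame,
    response: str,
    random_condition_slope: bool = False,
) -> MixedModelResult:
    """Linear mixed model on trial-level responses.

    Fixed effects: group and cognitive-load condition. Random effect: a
    participant intercept (optionally also a condition slope). Per-effect
    tests are Wald contrasts on the fixed effects reported on the F scale,
    with between-within (containment) denominator degrees of freedom:
    between-participant effects are tested against participants,
    within-participant effects against trials.
    """
    if response not in metrics.columns:
        raise ValueError(f"response {response!r} not in metrics table")
    data = metrics.dropna(subset=[response]).copy()
    re_formula = "~C(condition)" if random_condition_slope else "~1"
    formula = f"{response} ~ C(group) + C(condition)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                formula, data, groups=data["participant_id"], re_formula=re_formula
            )
            res = model.fit(reml=True)
        except Exception:
            if random_condition_slope:
                warnings.warn(
                    "random-slope fit failed; falling back to random intercept only",
                    stacklevel=2,
                )
                model = smf.mixedlm(formula, data, groups=data["participant_id"])
                res = model.fit(reml=True)
            else:
                raise

    fe_names = res.model.exog_names
    k_fe = len(fe_names)
    n_participants = data["participant_id"].nunique()
    exog = np.asarray(res.model.exog)
    pid_codes = pd.factorize(data["participant_id"])[0]
    effects = []
    for effect, prefix in (("group", "C(group)"), ("condition", "C(condition)")):
        idx = [i for i, nm in enumerate(fe_names) if nm.startswith(prefix)]
        if not idx:
            continue
        df_num = len(idx)
        # between-within (containment) denominator df: effects constant within
        # a participant are tested against participants, not trials
        between = all(
            pd.Series(exog[:, i]).groupby(pid_codes).nunique().max() == 1 for i in idx
        )
        if between:
            df_den = float(max(n_participants - df_num - 1, 1))
        else:
            df_den = float(max(len(data) - n_participants - (k_fe - 1), 1))
        L = np.zeros((df_num, len(res.params)))
        for row, i in enumerate(idx):
            L[row, i] = 1.0
        wt = res.wald_test(L, scalar=False)
        chi2 = float(np.squeeze(wt.statistic))
        f_stat = chi2 / df_num
        p = float(scipy.stats.f.sf(f_stat, df_num, df_den))
        effects.append(
            MixedModelEffect(
                effect=effect, f_stat=f_stat, df_num=df_num, df_den=df_den, p_value=p
            )
        )
    fixed = pd.DataFrame(
        {
            "term": fe_names,
            "estimate": [res.params[nm] for nm in fe_names],
            "se": [res.bse[nm] for nm in fe_names],
        }
    )
    return MixedModelResult(
        effects=effects, fixed_effects=fixed, converged=bool(res.converged), model=res
    )


def quiz_accuracy(quiz: pd.DataFrame) -> pd.Series:
    """Percent correct per group over all answers."""
    if quiz.empty:
        raise ValueError("quiz table is empty")
    return quiz.groupby("group")["correct"].mean() * 100.0
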