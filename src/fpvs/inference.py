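"""Group-level statistics and behavioural scoring.

Operates on tidy subject x condition tables of summed-harmonic amplitudes
(one row per cell) produced by the spectral module: paired t-tests for
condition contrasts, within-subject (repeated-measures) ANOVAs for the
orientation x hemisphere and identity x orientation designs, Bonferroni
pairwise comparisons, one-sample tests against zero, and scoring of the
fixation-cross colour-change task.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

VALUE = "summed_amplitude_uV"


@dataclass
class StatsResult:
    effect: str
    statistic: float
    dof: tuple[float, float]          # (numerator, denominator); (n-1, 0) for t
    p: float
    direction: str = ""
    correction: str = "none"          # none | bonferroni
    degenerate: bool = False          # zero-variance input
    gg_p: float | None = None         # Greenhouse-Geisser corrected p
    gg_epsilon: float | None = None

    def __post_init__(self) -> None:
        if not (self.degenerate or 0 <= self.p <= 1):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class BehavResult:
    accuracy: float                   # percent of targets answered in-window
    mean_rt: float | None             # ms over correct responses; None if no hits
    n_targets: int
    n_hits: int
    n_false_alarms: int = 0


def _pivot(table: pd.DataFrame, factor: str, value: str) -> pd.DataFrame:
    """subject x level matrix, averaging over any remaining factors."""
    wide = table.pivot_table(index="subject", columns=factor, values=value,
                             aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(
            f"incomplete design: subject(s) {missing} missing a level of {factor!r}"
        )
    return wide


def paired_test(
    table: pd.DataFrame,
    factor: str,
    levels: tuple[str, str],
    value: str = VALUE,
) -> StatsResult:
    """Two-tailed paired t-test between two levels of a within-subject factor."""
    wide = _pivot(table[table[factor].isin(levels)], factor, value)
    for lev in levels:
        if lev not in wide.columns:
            raise ValueError(f"level {lev!r} absent from factor {factor!r}")
    a, b = wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy()
    diff = a - b
    n = len(diff)
    if n < 2:
        raise ValueError("paired test needs at least 2 subjects")
    direction = f"{levels[0]} > {levels[1]}" if diff.mean() > 0 else (
        f"{levels[0]} < {levels[1]}" if diff.mean() < 0 else "equal")
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return StatsResult(f"{factor}: {levels[0]} vs {levels[1]}",
                               0.0, (n - 1, 0), 1.0, "equal")
        return StatsResult(f"{factor}: {levels[0]} vs {levels[1]}",
                           math.inf if diff[0] > 0 else -math.inf,
                           (n - 1, 0), 0.0, direction, degenerate=True)
    t, p = scipy.stats.ttest_rel(a, b)
    return StatsResult(
        f"{factor}: {levels[0]} vs {levels[1]}",
        float(t), (n - 1, 0), float(p), direction,
    )


def one_sample_vs_zero(
    table: pd.DataFrame,
    where: dict[str, str] | None = None,
    value: str = VALUE,
) -> StatsResult:
    """Two-tailed one-sample t-test of a cell's subject values against zero."""
    sub = table
    for col, lev in (where or {}).items():
        sub = sub[sub[col] == lev]
    vals = sub.groupby("subject")[value].mean().to_numpy()
    n = len(vals)
    if n < 2:
        raise ValueError("one-sample test needs at least 2 subjects")
    label = "vs zero" + (f" ({where})" if where else "")
    if np.allclose(vals, vals[0]):
        if vals[0] == 0:
            return StatsResult(label, 0.0, (n - 1, 0), 1.0, "equal")
        return StatsResult(label, math.copysign(math.inf, vals[0]),
                           (n - 1, 0), 0.0,
                           ">0" if vals[0] > 0 else "<0", degenerate=True)
    t, p = scipy.stats.ttest_1samp(vals, 0.0)
    return StatsResult(label, float(t), (n - 1, 0), float(p),
                       ">0" if vals.mean() > 0 else "<0")


def rm_anova(
    table: pd.DataFrame,
    factors: list[str],
    value: str = VALUE,
) -> list[StatsResult]:
    """Within-subject ANOVA via the standard repeated-measures decomposition.

    Supports one or two fully-crossed within-subject factors (2x2
    orientation x hemisphere, 6x2 identity x orientation, ...).  For factors
    or interactions with more than one numerator dof, a Greenhouse-Geisser
    corrected p-value is reported alongside the uncorrected one, since
    sphericity cannot be taken for granted with multi-level factors.
    """
    from statsmodels.stats.anova import AnovaRM

    cell = table.groupby(["subject", *factors], as_index=False)[value].mean()
    counts = cell.groupby(factors).size()
    if counts.nunique() != 1 or counts.iloc[0] != cell["subject"].nunique():
        raise ValueError("rm_anova requires a complete fully-crossed design")

    fit = AnovaRM(cell, depvar=value, subject="subject", within=factors).fit()
    results: list[StatsResult] = []
    for effect, row in fit.anova_table.iterrows():
        f_val = float(row["F Value"])
        df1, df2 = float(row["Num DF"]), float(row["Den DF"])
        res = StatsResult(effect, f_val, (df1, df2), float(row["Pr > F"]),
                          direction="")
        if df1 > 1 and ":" not in effect:
            eps = _gg_epsilon(cell, effect, value)
            res.gg_epsilon = eps
            res.gg_p = float(scipy.stats.f.sf(f_val, df1 * eps, df2 * eps))
        results.append(res)
    return results


def _gg_epsilon(cell: pd.DataFrame, factor: str, value: str) -> float:
    """Greenhouse-Geisser sphericity epsilon for one within-subject factor."""
    import pingouin  # deferred: heavy import

    sub = cell.groupby(["subject", factor], as_index=False)[value].mean()
    return float(
        pingouin.epsilon(sub, dv=value, within=factor, subject="subject",
                         correction="gg")
    )


def pairwise_bonferroni(
    table: pd.DataFrame,
    factor: str,
    value: str = VALUE,
) -> list[StatsResult]:
    """All pairwise paired t-tests between factor levels, Bonferroni adjusted.

    Raw p-values are multiplied by the number of comparisons and capped at 1.
    """
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    pairs = list(itertools.combinations(levels, 2))
    results = []
    for a, b in pairs:
        res = paired_test(table, factor, (a, b), value)
        res.p = min(1.0, res.p * len(pairs))
        res.correction = "bonferroni"
        results.append(res)
    return results


def score_fixation_task(
    target_times: np.ndarray,
    response_times: np.ndarray,
    window: tuple[float, float] = (0.150, 1.000),
) -> BehavResult:
    """Score the fixation-cross colour-change task.

    A response is matched to the most recent unmatched target if its latency
    falls within ``window`` (seconds, inclusive).  Accuracy is matched
    targets over all targets (percent); mean reaction time is over matched
    pairs (ms).  Unmatched responses are counted as false alarms but do not
    enter the accuracy.
    """
    targets = np.sort(np.asarray(target_times, dtype=float))
    responses = np.sort(np.asarray(response_times, dtype=float))
    matched = np.zeros(len(targets), dtype=bool)
    rts: list[float] = []
    false_alarms = 0
    for r in responses:
        idx = np.searchsorted(targets, r, side="right") - 1
        hit = False
        if idx >= 0 and not matched[idx]:
            latency = r - targets[idx]
            if window[0] <= latency <= window[1]:
                matched[idx] = True
                rts.append(latency)
                hit = True
        if not hit:
            false_alarms += 1
    n_targets = len(targets)
    n_hits = int(matched.sum())
    accuracy = 100.0 * n_hits / n_targets if n_targets else 0.0
    mean_rt = 1000.0 * float(np.mean(rts)) if rts else None
    return BehavResult(
        accuracy=accuracy,
        mean_rt=mean_rt,
        n_targets=n_targets,
        n_hits=n_hits,
        n_false_alarms=false_alarms,
    )
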