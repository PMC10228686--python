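"""Tear-wick and corneal-sensitivity endpoints with normality-gated statistics.

Two awake-animal endpoints accompany the imaging readouts:

* **Tear wick test** — an absorbent paper point in the lower lid for one
  minute; the wetted length (mm) measures tear production.  Summarized as
  mean ± SEM per group/day plus percent change from the baseline day.
* **Cochet-Bonnet aesthesiometry** — a nylon monofilament tapped on the
  central cornea 6 times at each tested length (3.5 down to 0.5 mm).
  Longer filament = lower applied force, so responding at a longer length
  means a more sensitive cornea.  A length counts as positive when ≥ 3 of
  6 taps elicit a blink; the sensitivity threshold is the longest positive
  length, or 0 if no length qualifies.

Group comparisons follow a normality-gated dispatch: Shapiro-Wilk per group
at α = 0.05, parametric tests (Student's t / one-way ANOVA) when every group
passes, rank-based analogues (Mann-Whitney / Kruskal-Wallis) otherwise.  The
named tests are delegated to scipy.stats; the dispatch rule is the content
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TESTED_LENGTHS_MM",
    "BlinkResponseTable",
    "GroupComparisonResult",
    "sensitivity_threshold",
    "blink_thresholds",
    "wick_summary",
    "group_compare",
]

TESTED_LENGTHS_MM = (3.5, 2.5, 2.0, 1.5, 1.0, 0.5)
N_TAPS = 6
POSITIVE_BLINKS = 3  # ≥ 3 of 6 taps


@dataclass
class BlinkResponseTable:
    """One animal/day: positive-blink count (of 6) at each tested filament length."""

    animal_id: str
    group: str
    day: int
    responses: dict[float, int]  # length_mm -> positives of 6

    def __post_init__(self) -> None:
        for length, pos in self.responses.items():
            if length not in TESTED_LENGTHS_MM:
                raise ValueError(f"untested filament length {length} mm")
            if not 0 <= pos <= N_TAPS:
                raise ValueError(f"positives must be 0..{N_TAPS}, got {pos}")


def sensitivity_threshold(table: BlinkResponseTable | dict[float, int]) -> float:
    """Longest filament length with ≥ 3/6 positive blinks; 0.0 if none qualifies.

    Longer filaments exert lower force, so the longest length still evoking
    a blink is the animal's sensitivity threshold.  Missing lengths are
    evaluated over those present, with a warning.
    """
    responses = table.responses if isinstance(table, BlinkResponseTable) else dict(table)
    if isinstance(table, dict):
        BlinkResponseTable("_", "_", 0, responses)  # validate
    if set(responses) != set(TESTED_LENGTHS_MM):
        warnings.warn("incomplete blink table: threshold computed over tested lengths present", stacklevel=2)
    qualifying = [length for length, pos in responses.items() if pos >= POSITIVE_BLINKS]
    return max(qualifying) if qualifying else 0.0


def blink_thresholds(blink_df: pd.DataFrame) -> pd.DataFrame:
    """Reduce a long blink table to one sensitivity threshold per animal/day.

    Expects columns animal_id, group, day, length_mm, positives.
    """
    rows = []
    for (animal, group, day), sub in blink_df.groupby(["animal_id", "group", "day"], sort=True):
        responses = dict(zip(sub["length_mm"].astype(float), sub["positives"].astype(int)))
        thr = sensitivity_threshold(BlinkResponseTable(str(animal), str(group), int(day), responses))
        rows.append({"animal_id": animal, "group": group, "day": day, "threshold_mm": thr})
    return pd.DataFrame(rows)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def wick_summary(measurements: pd.DataFrame, baseline_day: int = 0) -> pd.DataFrame:
    """Per-group/day mean ± SEM wick length plus percent change vs baseline.

    Expects columns animal_id, group, day, wick_mm.  Percent change is
    100·(mean_day − mean_baseline)/mean_baseline per group; a zero or
    missing baseline leaves it NaN with a ``flag``.
    """
    if (measurements["wick_mm"] < 0).any():
        raise ValueError("wick lengths must be >= 0")
    rows = []
    for group, sub in measurements.groupby("group", sort=True):
        base = sub.loc[sub["day"] == baseline_day, "wick_mm"].to_numpy()
        base_mean = float(base.mean()) if len(base) else np.nan
        for day, day_sub in sub.groupby("day", sort=True):
            v = day_sub["wick_mm"].to_numpy(float)
            flag = ""
            if len(base) == 0:
                flag = "no_baseline"
            elif base_mean == 0:
                flag = "zero_baseline"
            pct = np.nan if flag else 100.0 * (v.mean() - base_mean) / base_mean
            rows.append(
                {
                    "group": group,
                    "day": day,
                    "n": len(v),
                    "mean_mm": float(v.mean()),
                    "sem_mm": _sem(v),
                    "pct_change_vs_baseline": pct,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    summary: pd.DataFrame = field(repr=False)
    parametric: bool = True
    flags: list[str] = field(default_factory=list)


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant sample: normality test undefined, route nonparametric
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def group_compare(
    values,
    grouping,
    paired: bool = False,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Normality-gated two-or-more-group comparison.

    Shapiro-Wilk per group at ``alpha``; all pass -> Student's t-test (two
    groups) or one-way ANOVA; any fail -> Mann-Whitney U or Kruskal-Wallis.
    Paired two-group data use paired t / Wilcoxon signed-rank instead.
    Groups with n < 3 cannot be normality-tested and force the
    nonparametric branch with a warning.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = list(pd.unique(grouping))
    groups = [values[grouping == g] for g in labels]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flags: list[str] = []

    normality_p = {str(g): _shapiro_p(x) if len(x) >= 3 else np.nan for g, x in zip(labels, groups)}
    small = [g for g, x in zip(labels, groups) if len(x) < 3]
    if small:
        warnings.warn(f"groups {small} have n < 3: using nonparametric fallback", stacklevel=2)
        flags.append("insufficient_n")
        parametric = False
    else:
        parametric = all(p > alpha for p in normality_p.values())

    if all(np.ptp(x) == 0 for x in groups) and len({x[0] for x in groups if len(x)}) == 1:
        flags.append("degenerate")
        result_stat, result_p, name = 0.0, 1.0, "degenerate"
        parametric = False
    elif paired:
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("paired comparison needs exactly 2 equal-sized groups")
        if parametric:
            r = stats.ttest_rel(groups[0], groups[1])
            name = "paired t-test"
        else:
            r = stats.wilcoxon(groups[0], groups[1])
            name = "Wilcoxon signed-rank"
        result_stat, result_p = float(r.statistic), float(r.pvalue)
    elif len(groups) == 2:
        if parametric:
            r = stats.ttest_ind(groups[0], groups[1])
            name = "Student t-test"
        else:
            r = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            name = "Mann-Whitney U"
        result_stat, result_p = float(r.statistic), float(r.pvalue)
    else:
        if parametric:
            r = stats.f_oneway(*groups)
            name = "one-way ANOVA"
        else:
            r = stats.kruskal(*groups)
            name = "Kruskal-Wallis (ANOVA on ranks)"
        result_stat, result_p = float(r.statistic), float(r.pvalue)

    summary = pd.DataFrame(
        {
            "group": [str(g) for g in labels],
            "n": [len(x) for x in groups],
            "mean": [float(x.mean()) if len(x) else np.nan for x in groups],
            "sem": [_sem(x) for x in groups],
        }
    )
    return GroupComparisonResult(
        test_name=name,
        statistic=result_stat,
        p_value=result_p,
        normality_p=normality_p,
        summary=summary,
        parametric=parametric,
        flags=flags,
    )
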