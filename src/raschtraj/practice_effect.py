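"""Battery-level practice-effect adjudication.

A practice effect is score improvement on repeat testing due to prior
exposure rather than true change.  The decision rule: a trajectory group
shows a practice effect when its model-implied change over the study
period (slope x months) exceeds half a standard deviation of the baseline
total score; a change that exceeds the criterion but stays inside the
Bland-Altman 95% limits of agreement of first-vs-last scores is judged
within measurement error.  An overall paired one-tailed test of first vs
last session complements the group-level verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gbta import TrajectoryModel

__all__ = [
    "change_over_period",
    "half_sd_criterion",
    "criterion_from_sd",
    "BlandAltman",
    "bland_altman",
    "bland_altman_plot",
    "overall_first_last_test",
    "GroupVerdict",
    "PracticeEffectReport",
    "adjudicate",
]

LOA_Z = 1.96


def change_over_period(
    slope: float, slope_se: float, months: float
) -> tuple[float, float]:
    """Change over the study period and its SE: both scale by the months.

    A per-month slope of 0.36 over a 6-month study is a change of 2.16
    score units (SE scales identically).
    """
    if months <= 0:
        raise ValueError("months must be positive")
    return slope * months, slope_se * months


def criterion_from_sd(baseline_sd: float) -> float:
    """Half-SD criterion from a known baseline standard deviation."""
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be positive")
    return 0.5 * baseline_sd


def half_sd_criterion(baseline_scores) -> float:
    """Half the sample SD (n-1 denominator) of session-1 total scores."""
    x = np.asarray(baseline_scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 baseline scores")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("baseline scores have zero variance")
    return criterion_from_sd(sd)


@dataclass
class BlandAltman:
    """Limits-of-agreement summary of paired first/last measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    n_outside: int
    outside: np.ndarray
    person_ids: list
    differences: np.ndarray


def bland_altman(first, last, person_ids=None) -> BlandAltman:
    """Differences last - first with mean +/- 1.96 SD limits of agreement.

    Inputs must be paired (same persons, same order).  Pairs strictly
    outside the limits are counted; observations inside are within
    measurement error.
    """
    first = np.asarray(first, dtype=float)
    last = np.asarray(last, dtype=float)
    if first.shape != last.shape:
        raise ValueError("first and last must be paired (equal length)")
    if first.size < 3:
        raise ValueError("need at least 3 pairs")
    if person_ids is None:
        person_ids = list(range(first.size))
    elif len(person_ids) != first.size:
        raise ValueError("person_ids must match the number of pairs")
    d = last - first
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - LOA_Z * sd, mean + LOA_Z * sd
    outside = (d < lo) | (d > hi)
    return BlandAltman(
        mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
        n=int(d.size), n_outside=int(outside.sum()),
        outside=outside, person_ids=list(person_ids), differences=d,
    )


def bland_altman_plot(ba: BlandAltman, first, last, path) -> None:
    """Optional plot artifact: mean-vs-difference with limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = np.asarray(first, float)
    last = np.asarray(last, float)
    mean_xy = (first + last) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean_xy, ba.differences, s=18, alpha=0.7)
    for yv, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="gray")
    ax.set_xlabel("mean of first and last score")
    ax.set_ylabel("last - first")
    ax.set_title("Bland-Altman: first vs last session")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def overall_first_last_test(first, last) -> tuple[float, float]:
    """Paired mean-difference test, one-tailed toward improvement.

    Returns (t statistic, one-tailed p).  Degenerate zero-variance input
    resolves by the sign of the mean difference (all-zero differences give
    p = 0.5, the null value of a one-tailed test).
    """
    first = np.asarray(first, dtype=float)
    last = np.asarray(last, dtype=float)
    if first.shape != last.shape or first.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = last - first
    if np.std(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            return 0.0, 0.5
        return (np.inf, 0.0) if d.mean() > 0 else (-np.inf, 1.0)
    res = stats.ttest_rel(last, first, alternative="greater")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupVerdict:
    group: int
    membership_pct: float
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    change: float
    change_se: float
    exceeds_criterion: bool
    within_measurement_error: bool
    verdict: str


@dataclass
class PracticeEffectReport:
    groups: list[GroupVerdict]
    criterion_value: float
    period_months: float
    bland_altman: BlandAltman
    overall_statistic: float
    overall_p_one_tailed: float

    def to_markdown(self) -> str:
        lines = [
            "# Practice-effect report",
            "",
            "| Group | Membership (%) | Intercept (SE) | Slope (SE) | "
            "Change over time (SE) | Verdict |",
            "|---|---|---|---|---|---|",
        ]
        for g in self.groups:
            lines.append(
                f"| {g.group} | {g.membership_pct:.1f} | "
                f"{g.intercept:.1f} ({g.intercept_se:.2f}) | "
                f"{g.slope:.2f} ({g.slope_se:.2f}) | "
                f"{g.change:.2f} ({g.change_se:.2f}) | {g.verdict} |"
            )
        lines += [
            "",
            f"Criterion value: {self.criterion_value:.1f} (1/2 SD of the "
            "baseline total score)",
            "",
            "## Bland-Altman (last vs first session)",
            f"- mean difference {self.bland_altman.mean_diff:.2f}, "
            f"limits of agreement {self.bland_altman.loa_low:.2f} to "
            f"{self.bland_altman.loa_high:.2f}",
            f"- {self.bland_altman.n_outside} of {self.bland_altman.n} pairs "
            "outside the limits",
            "",
            f"Overall first-vs-last paired test: t = {self.overall_statistic:.2f},"
            f" one-tailed p = {self.overall_p_one_tailed:.3f}",
        ]
        return "\n".join(lines)


def adjudicate(
    model: TrajectoryModel,
    criterion: float,
    ba: BlandAltman,
    period_months: float = 6.0,
    overall: tuple[float, float] | None = None,
) -> PracticeEffectReport:
    """Per-group practice-effect verdicts against the half-SD criterion.

    A group exceeds the criterion when change (slope x months) is strictly
    greater than the criterion; an exceeding group whose assigned members
    include no Bland-Altman outliers is judged "change within measurement
    error", otherwise "practice effect".  Non-exceeding groups are
    "no practice effect".
    """
    labels = model.labels
    member_of = {pid: labels[i] for i, pid in enumerate(model.person_ids)}
    outliers_per_group = np.zeros(model.K, dtype=int)
    for pid, out in zip(ba.person_ids, ba.outside):
        if out and pid in member_of:
            outliers_per_group[member_of[pid]] += 1
    shares = model.group_shares
    groups = []
    for k in range(model.K):
        slope = float(model.slopes[k])
        slope_se = float(model.beta_se[k, 1]) if model.beta.shape[1] > 1 else 0.0
        change, change_se = change_over_period(slope, slope_se, period_months)
        exceeds = bool(change > criterion)
        within = bool(outliers_per_group[k] == 0)
        if not exceeds:
            verdict = "no practice effect"
        elif within:
            verdict = "change within measurement error"
        else:
            verdict = "practice effect"
        groups.append(
            GroupVerdict(
                group=k + 1,
                membership_pct=float(shares[k] * 100.0),
                intercept=float(model.intercepts[k]),
                intercept_se=float(model.beta_se[k, 0]),
                slope=slope,
                slope_se=slope_se,
                change=change,
                change_se=change_se,
                exceeds_criterion=exceeds,
                within_measurement_error=within,
                verdict=verdict,
            )
        )
    if overall is None:
        overall = (np.nan, np.nan)
    return PracticeEffectReport(
        groups=groups,
        criterion_value=float(criterion),
        period_months=float(period_months),
        bland_altman=ba,
        overall_statistic=float(overall[0]),
        overall_p_one_tailed=float(overall[1]),
    )
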