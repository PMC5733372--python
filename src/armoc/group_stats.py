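"""Welch's unequal-variance t-test comparison of fitted cost weights."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "welch_ttest", "compare_cohort"]


@dataclass(frozen=True)
class GroupComparison:
    """Welch test of one parameter between two independent groups."""

    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("t", "p", "df", "mean_a", "mean_b", "sd_a", "sd_b",
                 "n_a", "n_b")}


def welch_ttest(a, b) -> GroupComparison:
    """Two-sided Welch t-test without assuming equal variances or sizes.

    The statistic is ``(mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)``
    with Welch-Satterthwaite degrees of freedom; swapping the groups negates
    t and leaves p unchanged.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("a group has zero variance; Welch's test is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (a.size - 1) +
                               se2b ** 2 / (b.size - 1))
    return GroupComparison(t=float(res.statistic), p=float(res.pvalue),
                           df=float(df),
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                           n_a=int(a.size), n_b=int(b.size))


def compare_cohort(fits: pd.DataFrame,
                   group_col: str = "group",
                   groups: tuple[str, str] = ("normal", "patient"),
                   parameters: tuple[str, ...] = ("theta_p", "omega_p"),
                   ) -> dict:
    """Per-parameter Welch comparison of fitted weights between two groups.

    ``fits`` is a table with one row per subject containing the fitted
    parameters and a group label; both weights are tested separately (no
    multiple-testing correction, mirroring the two independent planned
    comparisons — interpret accordingly).  Returns a JSON-serialisable
    report with group summaries and the direction of each difference.
    """
    for g in groups:
        if (fits[group_col] == g).sum() < 2:
            raise ValueError(f"group '{g}' has fewer than two subjects")
    report: dict = {"groups": list(groups), "n": {
        g: int((fits[group_col] == g).sum()) for g in groups}}
    for param in parameters:
        a = fits.loc[fits[group_col] == groups[0], param].to_numpy(float)
        b = fits.loc[fits[group_col] == groups[1], param].to_numpy(float)
        cmp_ = welch_ttest(a, b)
        entry = cmp_.to_dict()
        entry["direction"] = (
            f"{param} higher in {groups[0] if cmp_.mean_a > cmp_.mean_b else groups[1]}")
        report[param] = entry
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def report_to_markdown(report: dict) -> str:
    lines = [f"| parameter | t | p | df | {report['groups'][0]} mean | "
             f"{report['groups'][1]} mean | direction |",
             "|---|---|---|---|---|---|---|"]
    for key, val in report.items():
        if not isinstance(val, dict) or "t" not in val:
            continue
        lines.append(
            f"| {key} | {val['t']:.3g} | {val['p']:.3g} | {val['df']:.1f} | "
            f"{val['mean_a']:.4g} | {val['mean_b']:.4g} | {val['direction']} |")
    return "\n".join(lines)
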