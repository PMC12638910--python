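"""Non-parametric two-sample comparisons with post-hoc effect size and power.

All stage-within-task and task-within-stage contrasts use the Wilcoxon
rank-sum (Mann-Whitney U) test: exact null enumeration for small
tie-free samples, the tie- and continuity-corrected normal approximation
otherwise.  Following the convention of post-hoc power calculators, the
observed effect is summarized as Cohen's d (pooled SD) and the achieved
power is that of the two-sided two-sample t test at the observed d and
group sizes, computed from the noncentral t distribution.  The
rank-biserial correlation is reported alongside d as the rank-native
effect measure.

No multiple-testing correction is applied by default (stars mark raw
p-values); a Benjamini-Hochberg adjusted column is available on request.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import emotiv_montage

__all__ = [
    "StatResult",
    "ranksum",
    "posthoc_power",
    "cohens_d",
    "ComparisonPlan",
    "run_comparisons",
    "HEMISPHERES",
]

log = logging.getLogger(__name__)

#: Hemisphere channel subsets of the 14-channel montage (no midline sites).
HEMISPHERES: dict[str, tuple[str, ...]] = {
    "whole": emotiv_montage().channel_names,
    "left": ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1"),
    "right": ("AF4", "F8", "F4", "FC6", "T8", "P8", "O2"),
}

#: Largest per-group size for which the exact null distribution is used.
EXACT_MAX_N = 10


@dataclass(frozen=True)
class StatResult:
    """One two-sample comparison: U statistic, p, effect size, power."""

    U: float
    p: float
    n1: int
    n2: int
    effect_size: float
    power: float
    rank_biserial: float
    method: str

    def stars(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled (ddof-1) standard deviation; NaN when degenerate."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        log.warning("zero pooled SD: Cohen's d undefined")
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def power_from_d(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Achieved power of the two-sided two-sample t test at effect size d.

    Uses the noncentral t distribution with noncentrality
    ``|d| * sqrt(n1 n2 / (n1 + n2))`` and ``n1 + n2 - 2`` degrees of
    freedom.  At d = 0 this returns alpha (the type-I rate).
    """
    if not np.isfinite(d):
        return float("nan")
    df = n1 + n2 - 2
    if df < 1:
        return float("nan")
    nc = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def posthoc_power(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> tuple[float, float]:
    """(Cohen's d, achieved power) for an observed two-group comparison."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("posthoc power needs at least 2 samples per group")
    d = cohens_d(x, y)
    return d, power_from_d(d, x.size, y.size, alpha)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def ranksum(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    With both groups of size <= 10 and no ties the exact null
    distribution of U is enumerated; otherwise the normal approximation
    with tie and continuity corrections is used.  Identical pooled
    values in both groups give p = 1.  The reported U is the statistic
    of the first sample.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        method = "degenerate"
        u1 = x.size * y.size / 2.0
        p = 1.0
    elif x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not _has_ties(x, y):
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u1, p = float(res.statistic), float(res.pvalue)
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u1, p = float(res.statistic), float(res.pvalue)
    d = cohens_d(x, y)
    power = power_from_d(d, x.size, y.size, alpha) if np.isfinite(d) else float("nan")
    rb = 2.0 * u1 / (x.size * y.size) - 1.0  # rank-biserial correlation
    return StatResult(U=u1, p=min(p, 1.0), n1=int(x.size), n2=int(y.size),
                      effect_size=d, power=power, rank_biserial=rb,
                      method=method)


@dataclass(frozen=True)
class ComparisonPlan:
    """Which pairwise contrasts to run on a feature table.

    ``grouping`` is ``"stages_within_task"`` (stage pairs compared
    separately for each task) or ``"tasks_within_stage"``.  ``measures``
    are band names (region-mean relative power), ``"amplitude"``
    (region-mean absolute voltage) or any numeric column of the table.
    ``regions`` select hemisphere channel subsets.
    """

    grouping: str = "stages_within_task"
    measures: tuple[str, ...] = ("alpha", "low_beta", "high_beta")
    regions: tuple[str, ...] = ("whole",)

    def __post_init__(self) -> None:
        if self.grouping not in ("stages_within_task", "tasks_within_stage"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        for r in self.regions:
            if r not in HEMISPHERES:
                raise ValueError(f"unknown region {r!r}")


def _measure_values(df: pd.DataFrame, measure: str, region: str) -> pd.Series:
    channels = HEMISPHERES[region]
    if measure == "amplitude":
        cols = [f"{c}_amp" for c in channels if f"{c}_amp" in df.columns]
    else:
        cols = [f"{c}_{measure}" for c in channels
                if f"{c}_{measure}" in df.columns]
    if cols:
        return df[cols].mean(axis=1)
    if measure in df.columns:
        return df[measure]
    raise KeyError(f"measure {measure!r} not resolvable in feature table")


def run_comparisons(
    features: pd.DataFrame,
    plan: ComparisonPlan = ComparisonPlan(),
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """All pairwise contrasts of the plan on a tidy feature table.

    Returns one row per (contrast, measure, region) with the rank-sum
    statistic, p-value, Cohen's d, achieved power, rank-biserial
    correlation and significance stars.  Contrasts with an empty group
    are skipped with a log entry.  With ``fdr`` a Benjamini-Hochberg
    adjusted p column is appended (off by default: raw per-contrast
    p-values are the reporting convention here).
    """
    if plan.grouping == "stages_within_task":
        within_col, between_col = "task", "stage"
    else:
        within_col, between_col = "stage", "task"
    rows = []
    for within_val, sub in features.groupby(within_col, sort=True):
        levels = sorted(sub[between_col].unique())
        for lev_a, lev_b in itertools.combinations(levels, 2):
            for measure in plan.measures:
                for region in plan.regions:
                    vals = _measure_values(sub, measure, region)
                    x = vals[sub[between_col] == lev_a].to_numpy()
                    y = vals[sub[between_col] == lev_b].to_numpy()
                    if x.size == 0 or y.size == 0:
                        log.info("skipping empty contrast %s=%s %s vs %s",
                                 within_col, within_val, lev_a, lev_b)
                        continue
                    r = ranksum(x, y, alpha=alpha)
                    rows.append({
                        within_col: within_val,
                        "contrast": f"{between_col}{lev_a} vs {between_col}{lev_b}",
                        "measure": measure,
                        "region": region,
                        "U": r.U, "p": r.p, "n1": r.n1, "n2": r.n2,
                        "d": r.effect_size, "power": r.power,
                        "rank_biserial": r.rank_biserial,
                        "method": r.method,
                        "stars": r.stars(),
                    })
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
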