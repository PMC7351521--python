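"""Target-attainment statistics and cross-cohort comparison.

The attainment metric is the achieved AUC divided by the predefined
target, times 100%.  Cohort summaries report the median and range, the
percent coefficient of variation, and the counts below / within / above
the 80-120% therapeutic band (inclusive at both boundaries).  Cohorts are
compared by one-way ANOVA with Bonferroni-adjusted pairwise t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import InvalidInputError
from .strategies import CourseRecord

__all__ = [
    "BAND_LO",
    "BAND_HI",
    "CohortResult",
    "ComparisonReport",
    "attainment_ratio",
    "band_counts",
    "percent_cv",
    "compare_cohorts",
    "build_report",
    "report_frame",
]

BAND_LO = 80.0
BAND_HI = 120.0


@dataclass(frozen=True)
class CohortResult:
    """Per-cohort attainment summary for one ratio kind (PK1 or cAUC)."""

    cohort: str
    kind: str                               # "pk1" | "cauc"
    n: int
    ratios: tuple[float, ...]               # percent
    median: float
    range: tuple[float, float]
    cv_percent: float | None                # None when n < 2
    n_below: int
    n_within: int
    n_above: int

    def __post_init__(self) -> None:
        if self.n_below + self.n_within + self.n_above != self.n:
            raise InvalidInputError("band counts must partition n")


@dataclass(frozen=True)
class ComparisonReport:
    """One-way ANOVA across cohorts plus Bonferroni pairwise t tests."""

    kind: str
    f_statistic: float
    p_value: float
    significant: bool                       # at alpha = 0.05
    pairwise: Mapping[tuple[str, str], float]   # Bonferroni-adjusted p, capped at 1


def attainment_ratio(auc_obs: float, auc_target: float) -> float:
    """100 x observed AUC / target AUC (percent)."""
    if auc_obs <= 0 or auc_target <= 0:
        raise InvalidInputError("AUCs must be > 0")
    return 100.0 * auc_obs / auc_target


def band_counts(ratios: Sequence[float]) -> tuple[int, int, int]:
    """(below, within, above) counts against the inclusive [80, 120]% band."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise InvalidInputError("ratios must be nonempty")
    below = int(np.sum(r < BAND_LO))
    above = int(np.sum(r > BAND_HI))
    return below, int(r.size) - below - above, above


def percent_cv(values: Sequence[float]) -> float:
    """Sample coefficient of variation: 100 x SD(n-1) / mean."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise InvalidInputError("percent CV needs >= 2 values")
    mean = v.mean()
    if mean <= 0:
        raise InvalidInputError("percent CV requires a positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def compare_cohorts(
    ratio_sets: Mapping[str, Sequence[float]],
    kind: str = "pk1",
    alpha: float = 0.05,
) -> ComparisonReport:
    """One-way ANOVA across cohorts with Bonferroni post hoc t tests.

    Pairwise two-sample t statistics have their p-values multiplied by the
    number of pairs and capped at 1.
    """
    if len(ratio_sets) < 2:
        raise InvalidInputError("need >= 2 cohorts to compare")
    groups = {k: np.asarray(list(v), dtype=float) for k, v in ratio_sets.items()}
    for name, g in groups.items():
        if g.size < 2:
            raise InvalidInputError(f"cohort {name!r} needs >= 2 values")
    f_stat, p_val = sps.f_oneway(*groups.values())
    pairs = list(combinations(sorted(groups), 2))
    pairwise = {}
    for a, b in pairs:
        _, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        pairwise[(a, b)] = min(1.0, float(p) * len(pairs))
    return ComparisonReport(
        kind=kind,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        significant=bool(p_val < alpha),
        pairwise=pairwise,
    )


def _summarize(cohort: str, kind: str, ratios: Sequence[float]) -> CohortResult:
    r = [float(x) for x in ratios]
    below, within, above = band_counts(r)
    return CohortResult(
        cohort=cohort,
        kind=kind,
        n=len(r),
        ratios=tuple(r),
        median=float(np.median(r)),
        range=(min(r), max(r)),
        cv_percent=percent_cv(r) if len(r) >= 2 else None,
        n_below=below,
        n_within=within,
        n_above=above,
    )


def build_report(
    courses: Sequence[CourseRecord],
) -> tuple[list[CohortResult], dict[str, ComparisonReport]]:
    """Cohort attainment tables plus cross-cohort comparisons.

    Produces one :class:`CohortResult` per (strategy, ratio kind) — the
    in-silico analogues of the clinical ratio/band tables — and, when at
    least two cohorts are present, ANOVA comparisons for both the
    first-assessment (PK1) and course-level (cAUC) ratios.
    """
    if not courses:
        raise InvalidInputError("no courses to report on")
    by_strategy: dict[str, list[CourseRecord]] = {}
    for c in courses:
        by_strategy.setdefault(c.strategy, []).append(c)

    results: list[CohortResult] = []
    pk1_sets: dict[str, list[float]] = {}
    cauc_sets: dict[str, list[float]] = {}
    for strat in sorted(by_strategy):
        recs = by_strategy[strat]
        pk1 = [c.pk1_ratio for c in recs if c.pk1_ratio is not None]
        cauc = [c.estimated_ratio for c in recs if np.isfinite(c.estimated_ratio)]
        if pk1:
            results.append(_summarize(strat, "pk1", pk1))
            pk1_sets[strat] = pk1
        if cauc:
            results.append(_summarize(strat, "cauc", cauc))
            cauc_sets[strat] = cauc

    comparisons: dict[str, ComparisonReport] = {}
    if len(pk1_sets) >= 2 and all(len(v) >= 2 for v in pk1_sets.values()):
        comparisons["pk1"] = compare_cohorts(pk1_sets, kind="pk1")
    if len(cauc_sets) >= 2 and all(len(v) >= 2 for v in cauc_sets.values()):
        comparisons["cauc"] = compare_cohorts(cauc_sets, kind="cauc")
    return results, comparisons


def report_frame(results: Sequence[CohortResult]) -> pd.DataFrame:
    """Tabular view of cohort results (one row per cohort x ratio kind)."""
    rows = []
    for r in results:
        rows.append(
            {
                "cohort": r.cohort,
                "kind": r.kind,
                "n": r.n,
                "median_ratio": r.median / 100.0,
                "ratio_lo": r.range[0] / 100.0,
                "ratio_hi": r.range[1] / 100.0,
                "cv_percent": r.cv_percent,
                "n_below_80": r.n_below,
                "n_within_80_120": r.n_within,
                "n_above_120": r.n_above,
                "pct_within": 100.0 * r.n_within / r.n,
            }
        )
    return pd.DataFrame(rows)
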