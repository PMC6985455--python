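"""Cell-level statistics: phenotype counts, proportions, speeds, MT rates.

Covers the cytometric side of a chromosomal-instability study: chi-squared
tests on mitotic/interphase phenotype contingency tables, aneuploid-cell
fraction summaries with Wilson confidence intervals, rank-sum tests on
per-track migration speeds, per-cell microtubule (MT) plus-end assembly
rate comparisons, and mitotic timing from per-cell phase timestamps.

Throughout, the statistical unit is the cell (phenotypes, timing, MT
rates) or the track (speeds), pooled across movies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import AnalysisError, DegenerateTableError

__all__ = [
    "chi_squared_test",
    "proportion_summary",
    "rank_sum_test",
    "mt_rate_comparison",
    "mitotic_timing_summary",
    "validate_count_table",
]

#: combined sample size up to which the rank-sum p-value is exact
EXACT_RANKSUM_MAX_N = 12


def validate_count_table(table: pd.DataFrame, n: Sequence[int] | None = None) -> None:
    """Check a condition x phenotype count table (non-negative, row sums)."""
    counts = table.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts < 0):
        raise DegenerateTableError("counts must be non-negative numbers")
    if n is not None:
        if not np.array_equal(counts.sum(axis=1), np.asarray(n)):
            raise DegenerateTableError("row sums do not match the stated n")


@dataclass
class Chi2Result:
    statistic: float
    dof: int
    p: float
    expected: np.ndarray = field(repr=False, default=None)


def chi_squared_test(table: pd.DataFrame, correction: bool = False) -> Chi2Result:
    """Pearson chi-squared test on a condition x phenotype count table.

    No Yates continuity correction by default.  A zero row or column
    marginal makes the table degenerate; expected counts below 5 trigger a
    warning but not an error.
    """
    validate_count_table(table)
    counts = np.asarray(table, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError("need at least 2 conditions and 2 phenotypes")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal (empty condition or phenotype)")
    stat, p, dof, expected = stats.chi2_contingency(counts, correction=correction)
    if np.any(expected < 5):
        warnings.warn(
            "expected count < 5 in at least one cell; chi-squared "
            "approximation may be poor",
            stacklevel=2,
        )
    return Chi2Result(statistic=float(stat), dof=int(dof), p=float(p), expected=expected)


@dataclass
class ProportionSummary:
    k: int
    n: int
    percent: float
    percent_rounded: int
    ci_low_pct: float
    ci_high_pct: float


def proportion_summary(k: int, n: int, confidence: float = 0.95) -> ProportionSummary:
    """Percentage k/n with a Wilson confidence interval.

    ``percent_rounded`` is the display value (nearest integer), e.g. 76
    aneuploid cells of 169 sequenced -> 45%.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    pct = 100.0 * k / n
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return ProportionSummary(
        k=k,
        n=n,
        percent=pct,
        percent_rounded=int(round(pct)),
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
    )


@dataclass
class RankSumResult:
    p: float
    statistic: float
    method: str
    tied: bool = False


def rank_sum_test(
    sample_a: Sequence[float], sample_b: Sequence[float], sides: str = "two"
) -> RankSumResult:
    """Wilcoxon-Mann-Whitney rank-sum test on two samples.

    Exact enumeration when the combined sample size is small (<= 12) and
    there are no ties; otherwise the normal approximation with tie
    correction.  If every value of both samples is identical the test is
    vacuous and p = 1 by convention (flagged).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise AnalysisError("need >= 1 value per sample")
    alternative = {"two": "two-sided", "one": "greater", "greater": "greater", "less": "less"}[sides]
    pooled = np.concatenate([a, b])
    tied = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return RankSumResult(p=1.0, statistic=a.size * b.size / 2.0, method="degenerate", tied=True)
    if np.array_equal(np.sort(a), np.sort(b)):
        return RankSumResult(p=1.0, statistic=a.size * b.size / 2.0, method="identical", tied=True)
    if pooled.size <= EXACT_RANKSUM_MAX_N and not tied:
        method = "exact"
    else:
        method = "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankSumResult(p=float(p), statistic=float(u), method=method, tied=tied)


@dataclass
class MTComparisonResult:
    cell_means_a: pd.Series
    cell_means_b: pd.Series
    statistic: float
    p: float
    mean_difference: float
    degenerate: bool = False


def mt_rate_comparison(
    rates: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    cell_column: str = "cell_id",
    condition_column: str = "condition",
    rate_column: str = "rate_um_per_min",
) -> MTComparisonResult:
    """Compare MT assembly rates between two conditions, cell as the unit.

    ``rates`` is long-format with one row per tracked MT (cell id,
    condition, rate in um/min).  Rates are first averaged within each cell
    (typically 20 MTs per cell); the unpaired two-sided t-test then runs on
    the per-cell means — individual MTs are never treated as independent
    observations.  Cells without any finite measurement are dropped with a
    warning.
    """
    sub = rates[rates[condition_column].isin([condition_a, condition_b])]
    finite = sub[np.isfinite(sub[rate_column].to_numpy(dtype=float))]
    dropped = set(zip(sub[condition_column], sub[cell_column])) - set(
        zip(finite[condition_column], finite[cell_column])
    )
    if dropped:
        warnings.warn(f"dropped {len(dropped)} cell(s) without MT measurements", stacklevel=2)
    means = finite.groupby([condition_column, cell_column])[rate_column].mean()
    try:
        ma = means.loc[condition_a]
        mb = means.loc[condition_b]
    except KeyError as exc:
        raise AnalysisError(f"missing condition {exc.args[0]!r}") from exc
    if ma.size < 2 or mb.size < 2:
        raise AnalysisError("need >= 2 cells per condition")
    diff = float(mb.mean() - ma.mean())
    if np.ptp(ma.to_numpy()) == 0 and np.ptp(mb.to_numpy()) == 0:
        return MTComparisonResult(
            cell_means_a=ma, cell_means_b=mb, statistic=np.nan,
            p=1.0 if diff == 0 else 0.0, mean_difference=diff, degenerate=True,
        )
    t, p = stats.ttest_ind(ma, mb, equal_var=False)
    return MTComparisonResult(
        cell_means_a=ma, cell_means_b=mb, statistic=float(t), p=float(p),
        mean_difference=diff,
    )


@dataclass
class TimingSummary:
    durations: pd.DataFrame
    medians: pd.DataFrame
    rejected: pd.DataFrame
    comparisons: dict


def mitotic_timing_summary(
    events: pd.DataFrame,
    group_column: str = "condition",
    test: str = "ranksum",
) -> TimingSummary:
    """Mitotic phase durations per cell and a between-group comparison.

    ``events`` needs per-cell timestamps (minutes) ``t_condensation``
    (first sign of DNA condensation), ``t_pre_anaphase`` (last point before
    anaphase) and ``t_decondensation``.  Durations are
    prophase->metaphase = t_pre_anaphase - t_condensation and
    anaphase->de-condensation = t_decondensation - t_pre_anaphase.
    Records with unordered timestamps are rejected with a reason.  Groups
    are compared pairwise per duration with a rank-sum test by default
    (``test="t"`` for Welch's t-test).
    """
    required = ["t_condensation", "t_pre_anaphase", "t_decondensation"]
    for col in required:
        if col not in events.columns:
            raise ValueError(f"events table lacks column {col!r}")
    t0, t1, t2 = (events[c].to_numpy(dtype=float) for c in required)
    ok = (t0 <= t1) & (t1 <= t2)
    rejected = events.loc[~ok].copy()
    rejected["reason"] = "timestamps not ordered (condensation <= pre-anaphase <= de-condensation)"
    kept = events.loc[ok].copy()
    kept["prophase_to_metaphase_min"] = t1[ok] - t0[ok]
    kept["anaphase_to_decondensation_min"] = t2[ok] - t1[ok]
    dur_cols = ["prophase_to_metaphase_min", "anaphase_to_decondensation_min"]
    medians = kept.groupby(group_column)[dur_cols].median()
    comparisons: dict = {}
    groups = sorted(kept[group_column].unique())
    for ga, gb in itertools.combinations(groups, 2):
        for col in dur_cols:
            va = kept.loc[kept[group_column] == ga, col].to_numpy()
            vb = kept.loc[kept[group_column] == gb, col].to_numpy()
            if test == "ranksum":
                p = rank_sum_test(va, vb).p
            elif test == "t":
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            comparisons[(ga, gb, col)] = p
    return TimingSummary(
        durations=kept, medians=medians, rejected=rejected, comparisons=comparisons
    )
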