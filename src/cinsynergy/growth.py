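"""Per-well growth summaries for confluency time series.

A proliferation screen produces one confluency-versus-time trace per well.
This module reduces each trace to the summary statistics used for hit
calling:

* area under the curve (AUC), either as the plain sum of confluencies over
  the shared time grid (the convention for evenly sampled live-cell imaging
  data) or as a trapezoid integral for unequal grids;
* the time point up to which growth is still exponential ("logarithmic
  growth cutoff"), detected as the largest expanding window over which a
  straight line fitted to log-confluency explains at least ``r2_min`` of the
  variance;
* slopes at that cutoff, both control-relative (confluency at the cutoff
  divided by the mean control confluency at the same time point) and the
  "manual" variant ``-ln(confluency fraction)/t_days``;
* control-relative AUC (each well divided by the mean vehicle-control AUC
  of its cell line).

Confluency is carried in percent; it is converted to a fraction before any
logarithm, and natural logarithms are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GridError, InsufficientDataError, NormalizationError

HOURS_PER_DAY = 24.0

#: label columns identifying a well in a tidy screen table
LABEL_COLUMNS = ["plate", "well", "cell_line", "drug", "dose_um", "bio_rep", "tech_rep"]
#: label columns identifying a biological condition
CONDITION_COLUMNS = ["cell_line", "drug", "dose_um"]


@dataclass
class WellSeries:
    """One well's confluency trace plus its condition labels.

    Parameters
    ----------
    times : array of float
        Sampling times in hours, strictly increasing, at least two points.
    confluency : array of float
        Confluency in percent; finite and non-negative.
    """

    times: np.ndarray
    confluency: np.ndarray
    cell_line: str = ""
    drug: str = "DMSO"
    dose_um: float = 0.0
    bio_rep: int = 1
    tech_rep: int = 1
    plate: str = "P1"
    well: str = "A01"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.confluency = np.asarray(self.confluency, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InsufficientDataError("a well series needs at least 2 time points")
        if self.times.shape != self.confluency.shape:
            raise ValueError("times and confluency must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.confluency)) or np.any(self.confluency < 0):
            raise ValueError("confluency must be finite and non-negative")

    def __len__(self) -> int:
        return self.times.size

    def nearest_index(self, t: float) -> int:
        """Index of the sampled time closest to *t* (ties toward earlier)."""
        return int(np.argmin(np.abs(self.times - t)))

    def replace_values(self, confluency: np.ndarray) -> "WellSeries":
        out = WellSeries(**{**self.__dict__, "confluency": np.asarray(confluency, float)})
        return out


@dataclass
class CutoffResult:
    """Outcome of exponential-phase detection."""

    time_h: float
    index: int
    r2: float
    low_quality: bool = False


@dataclass
class GrowthMetricRecord:
    """Per-well growth summaries."""

    cell_line: str
    drug: str
    dose_um: float
    bio_rep: int
    tech_rep: int
    auc: float
    cutoff_time_h: float = np.nan
    confluency_at_cutoff: float = np.nan
    slope_relative: float = np.nan
    slope_manual: float = np.nan
    relative_auc: float = np.nan
    cutoff_low_quality: bool = False
    plate: str = ""
    well: str = ""


def compute_auc(series: WellSeries, method: str = "sum") -> float:
    """Area under a confluency curve.

    ``method="sum"`` returns the sum of confluencies over time points
    (percent x time points); wells compared under this convention must share
    one time grid.  ``method="trapezoid"`` returns the trapezoid-rule
    integral in percent x hours and is safe on unequal grids.
    """
    if method == "sum":
        return float(np.sum(series.confluency))
    if method == "trapezoid":
        return float(np.trapezoid(series.confluency, series.times))
    raise ValueError(f"unknown AUC method {method!r}")


def _expanding_r2(t: np.ndarray, y: np.ndarray, min_points: int) -> np.ndarray:
    """R^2 of an OLS line over every expanding window [0, e] of (t, y).

    Returns an array aligned with ``t``; entries before the first full
    window are NaN.  Windows with zero variance in ``y`` (a flat series fits
    a horizontal line exactly) get R^2 = 1.
    """
    n = np.arange(1, t.size + 1, dtype=float)
    sx, sy = np.cumsum(t), np.cumsum(y)
    sxx, syy, sxy = np.cumsum(t * t), np.cumsum(y * y), np.cumsum(t * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_t = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        r2 = cov * cov / (var_t * var_y)
    # numerical guard: var_y == 0 -> perfect horizontal fit
    r2 = np.where(np.isclose(var_y, 0.0, atol=1e-12 * np.maximum(n * syy, 1.0)), 1.0, r2)
    r2[: min_points - 1] = np.nan
    return np.clip(r2, 0.0, 1.0)


def detect_exponential_cutoff(
    series: WellSeries, r2_min: float = 0.99, min_points: int = 4
) -> CutoffResult:
    """Find the end of the exponential (log-linear) growth phase.

    Starting at the first strictly positive observation, a least-squares
    line is fitted to (time, ln confluency) over every expanding window.
    The cutoff is the largest end time whose window still reaches
    ``R^2 >= r2_min``.  If no window qualifies, the time after
    ``min_points`` observations is returned with ``low_quality=True``.
    """
    positive = series.confluency > 0
    if not positive.any():
        raise InsufficientDataError("no positive confluency observations")
    i0 = int(np.argmax(positive))
    # restrict to the contiguous positive run (log is undefined beyond it)
    run_end = series.confluency.size
    later_zero = np.nonzero(~positive[i0:])[0]
    if later_zero.size:
        run_end = i0 + int(later_zero[0])
    t = series.times[i0:run_end]
    c = series.confluency[i0:run_end]
    if t.size < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} positive observations, got {t.size}"
        )
    r2 = _expanding_r2(t, np.log(c / 100.0), min_points)
    ok = np.nonzero(r2 >= r2_min)[0]
    if ok.size:
        e = int(ok[-1])
        return CutoffResult(time_h=float(t[e]), index=i0 + e, r2=float(r2[e]))
    e = min_points - 1
    return CutoffResult(
        time_h=float(t[e]), index=i0 + e, r2=float(r2[e]), low_quality=True
    )


def compute_relative_slope(
    series: WellSeries, control_series: Sequence[WellSeries], cutoff_time: float
) -> float:
    """Control-relative slope at a shared cutoff time.

    Because the cutoff time is held identical for a drug series and its
    vehicle controls, the slope ratio (confluency/time over the same time)
    reduces to the ratio of confluencies at the cutoff:
    ``C_drug(t*) / mean_controls C_control(t*)``.  The nearest sampled time
    is used on each grid (ties toward the earlier point).
    """
    if not control_series:
        raise NormalizationError("control series set is empty")
    c_drug = series.confluency[series.nearest_index(cutoff_time)]
    ctrl = np.array(
        [s.confluency[s.nearest_index(cutoff_time)] for s in control_series]
    )
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise NormalizationError("control mean confluency at cutoff is not positive")
    return float(c_drug / ctrl_mean)


def compute_manual_slope(series: WellSeries, cutoff_time: float) -> float:
    """Manual log-slope ``-ln(C_fraction(t*)) / t*_days``.

    Confluency is converted from percent to a fraction of full coverage
    before the logarithm; the cutoff time is converted from hours to days.
    """
    t_days = cutoff_time / HOURS_PER_DAY
    if t_days <= 0:
        raise ValueError("cutoff time must be positive")
    frac = series.confluency[series.nearest_index(cutoff_time)] / 100.0
    if frac <= 0:
        raise ValueError("confluency at cutoff is zero; log undefined")
    return float(-np.log(frac) / t_days)


def normalize_to_control(
    records: pd.DataFrame,
    control_drug: str = "DMSO",
    per: str = "cell_line",
    columns: Iterable[str] = ("auc",),
) -> pd.DataFrame:
    """Divide per-well metrics by the mean of the matching vehicle controls.

    ``per="cell_line"`` uses one pooled control mean per cell line (every
    AUC divided by the mean control AUC of its line).  ``per="bio_rep"``
    normalizes within each (cell line, biological replicate) pair, which
    keeps replicate values statistically independent when the normalized
    values are later compared between cell lines.

    Adds a ``relative_<column>`` column per requested column and returns a
    copy; control wells themselves get relative values with mean 1 within
    each normalization group.
    """
    if per == "cell_line":
        keys = ["cell_line"]
    elif per == "bio_rep":
        keys = ["cell_line", "bio_rep"]
    else:
        raise ValueError(f"unknown normalization scope {per!r}")
    out = records.copy()
    ctrl = records[records["drug"] == control_drug]
    missing = set(records["cell_line"]) - set(ctrl["cell_line"])
    if missing:
        raise NormalizationError(
            f"no {control_drug!r} control records for cell line(s): "
            + ", ".join(sorted(map(str, missing)))
        )
    for col in columns:
        means = ctrl.groupby(keys)[col].mean()
        denom = pd.MultiIndex.from_frame(records[keys]).map(means) if len(keys) > 1 \
            else records[keys[0]].map(means)
        denom = np.asarray(denom, dtype=float)
        if np.any(~np.isfinite(denom)) or np.any(denom == 0):
            raise NormalizationError(f"control mean of {col!r} missing or zero")
        out[f"relative_{col}"] = records[col].to_numpy(dtype=float) / denom
    return out


def split_time_windows(
    table: pd.DataFrame,
    boundaries_days: Sequence[float],
    edges: str = "halfopen",
    time_column: str = "time_h",
) -> list[tuple[str, pd.DataFrame]]:
    """Partition a tidy screen table into day windows.

    Boundaries are inner edges in days; a boundary at day 4 splits an 8-day
    screen into "d1-4" (t in [0, 96) h) and "d5-8" (t >= 96 h).  With
    ``edges="halfopen"`` each sample belongs to exactly one window; with
    ``edges="shared"`` a boundary that coincides with a sampled time is
    included in both adjacent windows, which makes trapezoid AUCs of the
    windows add up exactly to the full-curve AUC.  Empty windows are dropped
    with a warning.
    """
    if edges not in ("halfopen", "shared"):
        raise ValueError(f"unknown edge mode {edges!r}")
    t = table[time_column].to_numpy(dtype=float)
    bounds = sorted(float(b) * HOURS_PER_DAY for b in boundaries_days)
    edges_h = [-np.inf] + bounds + [np.inf]
    out: list[tuple[str, pd.DataFrame]] = []
    for lo, hi in zip(edges_h[:-1], edges_h[1:]):
        if edges == "halfopen":
            mask = (t >= lo) & (t < hi)
        else:
            mask = (t >= lo) & (t <= hi)
        lo_day = 0.0 if not np.isfinite(lo) else lo / HOURS_PER_DAY
        hi_day = t.max() / HOURS_PER_DAY if not np.isfinite(hi) else hi / HOURS_PER_DAY
        label = f"d{lo_day + 1:g}-{hi_day:g}"
        if not mask.any():
            warnings.warn(f"window {label} contains no samples; dropped", stacklevel=2)
            continue
        out.append((label, table.loc[mask]))
    return out


def stitch_passage(
    table: pd.DataFrame,
    passage_time_h: float,
    split_ratio: float,
    time_column: str = "time_h",
    value_column: str = "confluency_pct",
) -> pd.DataFrame:
    """Undo a 1:ratio passage by rescaling post-passage confluencies.

    Multiplies every observation at or after the passage time by the split
    ratio, producing a cumulative (virtual, possibly >100%) growth curve.
    """
    out = table.copy()
    late = out[time_column].to_numpy(dtype=float) >= passage_time_h
    out.loc[late, value_column] = out.loc[late, value_column] * split_ratio
    return out


def table_to_series(table: pd.DataFrame) -> list[WellSeries]:
    """Explode a tidy screen table into one :class:`WellSeries` per well."""
    present = [c for c in LABEL_COLUMNS if c in table.columns]
    out = []
    for key, grp in table.groupby(present, sort=True):
        grp = grp.sort_values("time_h")
        labels = dict(zip(present, key if isinstance(key, tuple) else (key,)))
        out.append(
            WellSeries(
                times=grp["time_h"].to_numpy(float),
                confluency=grp["confluency_pct"].to_numpy(float),
                **labels,
            )
        )
    return out


def metrics_table(
    screen: pd.DataFrame,
    auc_method: str = "sum",
    r2_min: float = 0.99,
    min_points: int = 4,
    vehicle: str = "DMSO",
    compute_slopes: bool = True,
    normalize: bool = True,
    normalize_per: str = "cell_line",
) -> pd.DataFrame:
    """Compute per-well growth metrics for a tidy screen table.

    The exponential cutoff is detected once per (cell line, drug, dose)
    condition on the replicate-mean curve, and — matching the convention
    that a drug and its vehicle control share one cutoff — the control mean
    confluency entering ``slope_relative`` is evaluated at that condition's
    cutoff time.
    """
    present = [c for c in LABEL_COLUMNS if c in screen.columns]
    wide = screen.pivot_table(
        index=present, columns="time_h", values="confluency_pct", aggfunc="first"
    ).sort_index(axis=1)
    times = wide.columns.to_numpy(dtype=float)
    values = wide.to_numpy(dtype=float)
    if auc_method == "sum":
        if np.isnan(values).any():
            raise GridError(
                "wells do not share one time grid; the sum AUC convention "
                "requires identical grids (use method='trapezoid')"
            )
        auc = values.sum(axis=1)
    elif auc_method == "trapezoid":
        auc = np.array(
            [
                np.trapezoid(row[~np.isnan(row)], times[~np.isnan(row)])
                for row in values
            ]
        )
    else:
        raise ValueError(f"unknown AUC method {auc_method!r}")

    rec = wide.index.to_frame(index=False)
    rec["auc"] = auc

    if compute_slopes:
        cond_mean = (
            screen.groupby(CONDITION_COLUMNS + ["time_h"])["confluency_pct"]
            .mean()
            .reset_index()
        )
        cutoff_by_cond: dict[tuple, CutoffResult] = {}
        for key, grp in cond_mean.groupby(CONDITION_COLUMNS, sort=True):
            grp = grp.sort_values("time_h")
            mean_series = WellSeries(
                times=grp["time_h"].to_numpy(float),
                confluency=grp["confluency_pct"].to_numpy(float),
            )
            cutoff_by_cond[key] = detect_exponential_cutoff(
                mean_series, r2_min=r2_min, min_points=min_points
            )
        # control mean confluency per cell line evaluated on its mean curve
        ctrl_curves = {
            line: grp.sort_values("time_h")
            for line, grp in cond_mean[cond_mean["drug"] == vehicle].groupby("cell_line")
        }
        cut_t, cut_c, slope_rel, slope_man, low_q = [], [], [], [], []
        for row, vals in zip(rec.itertuples(index=False), values):
            key = (row.cell_line, row.drug, row.dose_um)
            cut = cutoff_by_cond[key]
            idx = int(np.argmin(np.abs(times - cut.time_h)))
            c_at = vals[idx]
            cut_t.append(cut.time_h)
            cut_c.append(c_at)
            low_q.append(cut.low_quality)
            if row.cell_line in ctrl_curves:
                ctrl = ctrl_curves[row.cell_line]
                ct = ctrl["time_h"].to_numpy(float)
                cmean = ctrl["confluency_pct"].to_numpy(float)[
                    int(np.argmin(np.abs(ct - cut.time_h)))
                ]
                slope_rel.append(c_at / cmean if cmean > 0 else np.nan)
            else:
                slope_rel.append(np.nan)
            t_days = cut.time_h / HOURS_PER_DAY
            slope_man.append(
                -np.log(c_at / 100.0) / t_days if (c_at > 0 and t_days > 0) else np.nan
            )
        rec["cutoff_time_h"] = cut_t
        rec["confluency_at_cutoff"] = cut_c
        rec["slope_relative"] = slope_rel
        rec["slope_manual"] = slope_man
        rec["cutoff_low_quality"] = low_q

    if normalize:
        rec = normalize_to_control(
            rec, control_drug=vehicle, per=normalize_per, columns=("auc",)
        )
    return rec
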