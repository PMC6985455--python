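"""Per-drug differential sensitivity between two cell lines.

For every drug, control-relative growth metrics (relative AUC or relative
slope) of two cell lines are compared with a t-test; the effect size is the
log2 ratio of group means, p-values are Bonferroni-corrected over the drug
family, and hits are drugs passing both an effect and a corrected
significance threshold (volcano-plot style).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .growth import metrics_table, normalize_to_control

__all__ = [
    "compare_cell_lines",
    "bonferroni_adjust",
    "build_volcano_table",
    "DifferentialScreen",
    "DifferentialResults",
]

_ALTERNATIVES = {
    "two": "two-sided",
    "two-sided": "two-sided",
    "one": "greater",
    "greater": "greater",
    "less": "less",
}


class ComparisonResult(NamedTuple):
    effect: float
    p: float
    degenerate: bool = False


def compare_cell_lines(
    values_a: Sequence[float],
    values_b: Sequence[float],
    sides: str = "two",
    equal_var: bool = False,
) -> ComparisonResult:
    """Effect (log2 mean ratio) and t-test p-value for two metric samples.

    Welch's unequal-variance t-test is the default; set ``equal_var=True``
    for the pooled Student variant.  If both groups have zero variance and
    equal means the comparison is degenerate and p = 1 by convention.
    Non-positive group means leave the log-ratio effect undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("need >= 2 values per group")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a <= 0 or mean_b <= 0:
        raise AnalysisError("log2 effect undefined for non-positive group means")
    effect = float(np.log2(mean_a / mean_b))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return ComparisonResult(effect=0.0, p=1.0, degenerate=True)
        return ComparisonResult(effect=effect, p=0.0, degenerate=True)
    _, p = stats.ttest_ind(
        a, b, equal_var=equal_var, alternative=_ALTERNATIVES[sides]
    )
    return ComparisonResult(effect=effect, p=float(p))


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    if m < p.size:
        raise ValueError("family size smaller than the number of tests")
    return np.minimum(1.0, m * p)


def build_volcano_table(
    records: pd.DataFrame, effect_min: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Annotate differential records with hit flags and plot columns.

    A hit has \\|effect\\| >= ``effect_min`` and Bonferroni-corrected
    p < ``alpha``.  Adds ``neg_log10_p`` (of the corrected p) for plotting.
    """
    out = records.copy()
    p = out["p_bonferroni"].to_numpy(dtype=float)
    out["neg_log10_p"] = -np.log10(np.maximum(p, 1e-300))
    out["hit"] = (np.abs(out["effect"].to_numpy(dtype=float)) >= effect_min) & (
        p < alpha
    )
    return out


class DifferentialScreen:
    """Model object: per-drug sensitivity difference between two cell lines.

    Built from either a tidy screen table (``from_screen``) or a per-well
    metrics table (``from_metrics``).  ``metric="auc"`` compares
    control-relative AUC; ``metric="slope"`` compares the control-relative
    slope at the exponential-growth cutoff.

    ``replicate_unit="bio"`` (default) averages technical replicates within
    each biological replicate before testing; ``"well"`` treats all wells
    as independent.  ``normalize_per="bio_rep"`` (default) divides by each
    biological replicate's own control mean, which keeps the replicate
    values independent so the t-test and the Bonferroni family-wise error
    control stay calibrated; ``"cell_line"`` reproduces the pooled
    normalization convention (one control mean per line).
    """

    def __init__(
        self,
        metrics: pd.DataFrame,
        line_a: str,
        line_b: str,
        metric: str = "auc",
        vehicle: str = "DMSO",
        replicate_unit: str = "bio",
        normalize_per: str = "bio_rep",
        sides: str = "two",
        equal_var: bool = False,
        family_size: int | None = None,
    ) -> None:
        if metric not in ("auc", "slope"):
            raise ValueError("metric must be 'auc' or 'slope'")
        if replicate_unit not in ("bio", "well"):
            raise ValueError("replicate_unit must be 'bio' or 'well'")
        self.metrics = metrics
        self.line_a, self.line_b = line_a, line_b
        self.metric = metric
        self.vehicle = vehicle
        self.replicate_unit = replicate_unit
        self.normalize_per = normalize_per
        self.sides = sides
        self.equal_var = equal_var
        self.family_size = family_size

    @classmethod
    def from_metrics(cls, metrics: pd.DataFrame, **kwargs) -> "DifferentialScreen":
        return cls(metrics, **kwargs)

    @classmethod
    def from_screen(
        cls,
        screen: pd.DataFrame,
        line_a: str,
        line_b: str,
        metric: str = "auc",
        auc_method: str = "sum",
        r2_min: float = 0.99,
        vehicle: str = "DMSO",
        **kwargs,
    ) -> "DifferentialScreen":
        mt = metrics_table(
            screen,
            auc_method=auc_method,
            r2_min=r2_min,
            vehicle=vehicle,
            compute_slopes=(metric == "slope"),
            normalize=False,
        )
        return cls(mt, line_a, line_b, metric=metric, vehicle=vehicle, **kwargs)

    # -- internals ---------------------------------------------------------
    def _replicate_values(self) -> pd.DataFrame:
        """Control-relative replicate values, one row per (drug, line, rep)."""
        raw_col = "auc" if self.metric == "auc" else "confluency_at_cutoff"
        if raw_col not in self.metrics.columns:
            raise AnalysisError(
                f"metrics table lacks the {raw_col!r} column needed for "
                f"metric={self.metric!r}"
            )
        sub = self.metrics[
            self.metrics["cell_line"].isin([self.line_a, self.line_b])
        ].copy()
        norm = normalize_to_control(
            sub, control_drug=self.vehicle, per=self.normalize_per, columns=(raw_col,)
        )
        rel = f"relative_{raw_col}"
        if self.replicate_unit == "bio":
            grouped = (
                norm.groupby(["cell_line", "drug", "bio_rep"], sort=True)[rel]
                .mean()
                .reset_index()
            )
        else:
            grouped = norm[["cell_line", "drug", "bio_rep", "tech_rep", rel]]
        return grouped.rename(columns={rel: "value"})

    def fit(self) -> "DifferentialResults":
        values = self._replicate_values()
        drugs = sorted(set(values["drug"]) - {self.vehicle})
        if not drugs:
            raise AnalysisError("no non-vehicle drugs to test")
        rows = []
        for drug in drugs:
            va = values.loc[
                (values["drug"] == drug) & (values["cell_line"] == self.line_a),
                "value",
            ].to_numpy()
            vb = values.loc[
                (values["drug"] == drug) & (values["cell_line"] == self.line_b),
                "value",
            ].to_numpy()
            res = compare_cell_lines(
                va, vb, sides=self.sides, equal_var=self.equal_var
            )
            rows.append(
                {
                    "drug": drug,
                    "metric": f"relative_{self.metric}",
                    "effect": res.effect,
                    "p_raw": res.p,
                    "n_a": va.size,
                    "n_b": vb.size,
                    "degenerate": res.degenerate,
                }
            )
        table = pd.DataFrame(rows)
        m = self.family_size if self.family_size is not None else len(drugs)
        table["p_bonferroni"] = bonferroni_adjust(table["p_raw"].to_numpy(), m=m)
        return DifferentialResults(self, table, family_size=m)


class DifferentialResults:
    """Per-drug effects, raw and Bonferroni-corrected p-values."""

    def __init__(
        self, model: DifferentialScreen, table: pd.DataFrame, family_size: int
    ) -> None:
        self.model = model
        self.table = table
        self.family_size = family_size

    def hits(self, effect_min: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
        annotated = build_volcano_table(self.table, effect_min=effect_min, alpha=alpha)
        return annotated[annotated["hit"]]

    def volcano_table(self, effect_min: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
        return build_volcano_table(self.table, effect_min=effect_min, alpha=alpha)

    def plot_volcano(self, effect_min: float = 1.0, alpha: float = 0.05, ax=None):
        """Volcano plot: log2 effect vs -log10 corrected p, hits highlighted."""
        import matplotlib.pyplot as plt

        tab = self.volcano_table(effect_min=effect_min, alpha=alpha)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        colors = np.where(tab["hit"], "tab:blue", "0.6")
        ax.scatter(tab["effect"], tab["neg_log10_p"], c=colors, s=18)
        ax.axhline(-np.log10(alpha), ls="--", c="0.8", lw=1)
        for sgn in (-1, 1):
            ax.axvline(sgn * effect_min, ls="--", c="0.8", lw=1)
        ax.set_xlabel(
            f"log2({self.model.line_a} / {self.model.line_b}) "
            f"relative {self.model.metric}"
        )
        ax.set_ylabel("-log10 Bonferroni p")
        return ax

    def summary(self) -> str:
        lines = [
            f"Differential sensitivity: {self.model.line_a} vs {self.model.line_b}"
            f" on relative {self.model.metric}",
            f"replicate unit: {self.model.replicate_unit},"
            f" normalization: per {self.model.normalize_per},"
            f" Bonferroni family size: {self.family_size}",
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
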