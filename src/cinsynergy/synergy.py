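"""Bliss-independence synergy between a drug and a second perturbation.

The readout of the screen is cumulative growth (AUC of confluency over
time).  For a drug *a* and a perturbation *b* (a genotype such as an
induced checkpoint knockdown, or a second drug), fractional growth
inhibitions are defined against the unperturbed vehicle reference:

    F = 1 - AUC(treated) / AUC(reference)

Under Bliss independence the two effects combine as

    E[F_ab] = Fa + Fb - Fa * Fb

and the synergy signal is the excess of the observed combined inhibition
over this expectation.  Both the absolute excess (in inhibition fraction,
i.e. percentage points when multiplied by 100) and the relative excess
(excess / expected, "X% stronger than additive") are reported, together
with a replicate-level t-test of the observed inhibitions against the
expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, DesignError
from . import growth as _growth

__all__ = [
    "fractional_inhibition",
    "expected_inhibition",
    "synergy_test",
    "bliss_excess",
    "SynergyRecord",
    "BlissSynergy",
    "SynergyResults",
]


def fractional_inhibition(auc_treated: float, auc_reference: float):
    """Fractional growth inhibition 1 - AUC(treated)/AUC(reference).

    Values are in (-inf, 1]; negative values mean growth stimulation and
    are permitted (a warning is emitted) but never silently clipped here.
    """
    auc_reference = np.asarray(auc_reference, dtype=float)
    if np.any(auc_reference <= 0):
        raise AnalysisError("reference AUC must be positive")
    f = 1.0 - np.asarray(auc_treated, dtype=float) / auc_reference
    if np.any(np.asarray(f) < 0):
        warnings.warn(
            "negative fractional inhibition (growth stimulation)", stacklevel=2
        )
    return float(f) if np.ndim(f) == 0 else f


def expected_inhibition(fa: float, fb: float) -> float:
    """Bliss expected combined inhibition Fa + Fb - Fa*Fb.

    Inputs are clipped to [0, 1] inside the formula only; callers keep the
    raw values for reporting.
    """
    fa = float(np.clip(fa, 0.0, 1.0))
    fb = float(np.clip(fb, 0.0, 1.0))
    return fa + fb - fa * fb


@dataclass
class SynergyTestResult:
    p: float
    statistic: float
    degenerate: bool = False


def synergy_test(
    per_replicate_observed: Sequence[float], expected: float, sides: str = "two"
) -> SynergyTestResult:
    """One-sample t-test of replicate observed inhibitions against expected.

    ``sides="two"`` (default) tests for any deviation from additivity;
    ``sides="greater"`` tests for synergy only (observed > expected).  With
    zero variance across replicates the t statistic is undefined; the
    decision degenerates to exact equality (p = 1 if all observed equal the
    expectation, else p = 0) and is flagged.
    """
    obs = np.asarray(per_replicate_observed, dtype=float)
    if obs.size < 2:
        raise AnalysisError("need >= 2 replicate observations for the synergy test")
    alternative = {"two": "two-sided", "one": "greater", "greater": "greater", "less": "less"}[sides]
    if np.ptp(obs) == 0:
        return SynergyTestResult(
            p=1.0 if obs[0] == expected else 0.0, statistic=np.nan, degenerate=True
        )
    t, p = stats.ttest_1samp(obs, popmean=expected, alternative=alternative)
    return SynergyTestResult(p=float(p), statistic=float(t))


@dataclass
class SynergyRecord:
    """Bliss quantities for one drug x perturbation (x time window)."""

    drug: str
    perturbation: str
    window: str
    fa: float
    fb: float
    expected: float
    observed: float
    excess: float
    excess_relative: float
    p: float
    n: int
    statistic: float = np.nan
    degenerate: bool = False
    stimulation_flag: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _group_aucs(
    table: pd.DataFrame,
    cell_line: str,
    drug: str,
    auc_method: str,
) -> pd.Series:
    sub = table[(table["cell_line"] == cell_line) & (table["drug"] == drug)]
    if sub.empty:
        raise DesignError(f"missing condition group: ({cell_line!r}, {drug!r})")
    keys = [c for c in _growth.LABEL_COLUMNS if c in sub.columns]
    if auc_method == "sum":
        return sub.groupby(keys, sort=True)["confluency_pct"].sum()
    wide = sub.pivot_table(index=keys, columns="time_h", values="confluency_pct")
    times = wide.columns.to_numpy(dtype=float)
    return pd.Series(
        np.trapezoid(wide.to_numpy(dtype=float), times, axis=1), index=wide.index
    )


def bliss_excess(
    screen: pd.DataFrame,
    drug: str,
    perturbation: str,
    reference_line: str,
    vehicle: str = "DMSO",
    auc_method: str = "sum",
    sides: str = "two",
    replicate_mode: str = "well",
    window: str = "full",
    n_boot: int | None = None,
    rng: np.random.Generator | None = None,
) -> SynergyRecord:
    """Bliss excess of one drug x perturbation pair from a tidy screen table.

    The four condition groups are: reference (reference line + vehicle),
    drug alone (reference line + drug), perturbation alone (perturbed line
    + vehicle) and combination (perturbed line + drug).  All four AUCs are
    computed with one method over the same time window.

    ``replicate_mode`` controls how replicates enter the significance test:

    * ``"well"`` — each combination well's AUC is set against the mean
      reference AUC to give a replicate-level observed inhibition, and the
      one-sample t-test compares those to the expected inhibition computed
      from the mean Fa and mean Fb.  This treats the expectation as known;
      because Fa, Fb and the reference mean carry sampling noise of the
      same order as the combination wells, the test is anticonservative at
      small replicate numbers.
    * ``"paired"`` — wells are matched across the four groups by
      (bio_rep, tech_rep); each replicate yields its own Fa, Fb, expected
      and observed value, and the per-replicate excess is tested against
      zero.  This propagates the noise of all four groups and is the
      calibrated choice.
    * ``"bootstrap"`` — point estimates as in ``"well"``; the p-value comes
      from resampling wells within all four groups (``n_boot`` draws).
    """
    aucs = {
        "ref": _group_aucs(screen, reference_line, vehicle, auc_method),
        "a": _group_aucs(screen, reference_line, drug, auc_method),
        "b": _group_aucs(screen, perturbation, vehicle, auc_method),
        "ab": _group_aucs(screen, perturbation, drug, auc_method),
    }
    ref_mean = float(aucs["ref"].mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = fractional_inhibition(float(aucs["a"].mean()), ref_mean)
        fb = fractional_inhibition(float(aucs["b"].mean()), ref_mean)
        observed_wells = np.asarray(
            fractional_inhibition(aucs["ab"].to_numpy(dtype=float), ref_mean)
        )
    expected = expected_inhibition(fa, fb)
    observed = float(observed_wells.mean())
    excess = observed - expected

    if replicate_mode == "well":
        test = synergy_test(observed_wells, expected, sides=sides)
    elif replicate_mode == "paired":
        per_rep = _paired_excess(aucs)
        test = synergy_test(per_rep, 0.0, sides=sides)
    elif replicate_mode == "bootstrap":
        test = _bootstrap_test(aucs, sides=sides, n_boot=n_boot or 2000, rng=rng)
    else:
        raise ValueError(f"unknown replicate mode {replicate_mode!r}")

    return SynergyRecord(
        drug=drug,
        perturbation=perturbation,
        window=window,
        fa=fa,
        fb=fb,
        expected=expected,
        observed=observed,
        excess=excess,
        excess_relative=excess / expected if expected != 0 else np.nan,
        p=test.p,
        statistic=test.statistic,
        n=int(observed_wells.size),
        degenerate=test.degenerate,
        stimulation_flag=bool(min(fa, fb, observed) < 0),
    )


def _replicate_frame(aucs: dict[str, pd.Series]) -> pd.DataFrame:
    """Align the four groups' per-well AUCs on (bio_rep, tech_rep)."""
    cols = {}
    for key, s in aucs.items():
        df = s.reset_index()
        if not {"bio_rep", "tech_rep"}.issubset(df.columns):
            raise AnalysisError(
                "paired replicate mode requires bio_rep and tech_rep labels"
            )
        cols[key] = df.set_index(["bio_rep", "tech_rep"])[s.name or 0]
    frame = pd.DataFrame(cols).dropna()
    if len(frame) < 2:
        raise AnalysisError("fewer than 2 matched replicates across the four groups")
    return frame


def _paired_excess(aucs: dict[str, pd.Series]) -> np.ndarray:
    frame = _replicate_frame(aucs)
    ref = frame["ref"].to_numpy()
    fa = 1.0 - frame["a"].to_numpy() / ref
    fb = 1.0 - frame["b"].to_numpy() / ref
    obs = 1.0 - frame["ab"].to_numpy() / ref
    exp = np.clip(fa, 0, 1) + np.clip(fb, 0, 1) - np.clip(fa, 0, 1) * np.clip(fb, 0, 1)
    return obs - exp


def _bootstrap_test(
    aucs: dict[str, pd.Series],
    sides: str,
    n_boot: int,
    rng: np.random.Generator | None,
) -> SynergyTestResult:
    rng = rng if rng is not None else np.random.default_rng(0)
    arrays = {k: s.to_numpy(dtype=float) for k, s in aucs.items()}

    def excess_of(sample: dict[str, np.ndarray]) -> float:
        ref = sample["ref"].mean()
        fa = 1.0 - sample["a"].mean() / ref
        fb = 1.0 - sample["b"].mean() / ref
        obs = 1.0 - sample["ab"].mean() / ref
        return obs - expected_inhibition(fa, fb)

    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = excess_of(
            {k: rng.choice(v, size=v.size, replace=True) for k, v in arrays.items()}
        )
    p_le = (1 + np.sum(boots <= 0)) / (n_boot + 1)
    p_ge = (1 + np.sum(boots >= 0)) / (n_boot + 1)
    if sides in ("two",):
        p = min(1.0, 2 * min(p_le, p_ge))
    elif sides in ("one", "greater"):
        p = p_le  # synergy: how often the resampled excess falls at/below 0
    else:
        p = p_ge
    return SynergyTestResult(p=float(p), statistic=float(np.mean(boots)))


class BlissSynergy:
    """Model object: Bliss synergy for drug x perturbation pairs of a screen.

    Parameters
    ----------
    screen : tidy screen table (see :mod:`cinsynergy.io`)
    perturbation : cell line / genotype level acting as the second
        perturbation (e.g. an induced knockdown line)
    reference_line : unperturbed line; reference wells are
        (reference_line, vehicle)
    drugs : drugs to score (default: all non-vehicle drugs present)
    windows : optional day boundaries (e.g. ``[4]``) to score day windows
        separately, each against its own window reference AUCs
    """

    def __init__(
        self,
        screen: pd.DataFrame,
        perturbation: str,
        reference_line: str,
        drugs: Sequence[str] | None = None,
        vehicle: str = "DMSO",
        auc_method: str = "sum",
        sides: str = "two",
        replicate_mode: str = "well",
        windows: Sequence[float] | None = None,
        n_boot: int | None = None,
        seed: int = 0,
    ) -> None:
        self.screen = screen
        self.perturbation = perturbation
        self.reference_line = reference_line
        self.vehicle = vehicle
        self.drugs = list(drugs) if drugs is not None else sorted(
            set(screen["drug"]) - {vehicle}
        )
        self.auc_method = auc_method
        self.sides = sides
        self.replicate_mode = replicate_mode
        self.windows = list(windows) if windows is not None else None
        self.n_boot = n_boot
        self.seed = seed

    @classmethod
    def from_dataframe(cls, screen: pd.DataFrame, **kwargs) -> "BlissSynergy":
        return cls(screen, **kwargs)

    def fit(self) -> "SynergyResults":
        rng = np.random.default_rng(self.seed)
        tables: list[tuple[str, pd.DataFrame]] = [("full", self.screen)]
        if self.windows:
            tables += _growth.split_time_windows(self.screen, self.windows)
        records = []
        for label, tab in tables:
            for drug in self.drugs:
                records.append(
                    bliss_excess(
                        tab,
                        drug=drug,
                        perturbation=self.perturbation,
                        reference_line=self.reference_line,
                        vehicle=self.vehicle,
                        auc_method=self.auc_method,
                        sides=self.sides,
                        replicate_mode=self.replicate_mode,
                        window=label,
                        n_boot=self.n_boot,
                        rng=rng,
                    )
                )
        return SynergyResults(self, records)


class SynergyResults:
    """Fitted Bliss synergy estimates with replicate-level significance."""

    def __init__(self, model: BlissSynergy, records: list[SynergyRecord]) -> None:
        self.model = model
        self.records = pd.DataFrame([r.as_dict() for r in records])

    def summary(self) -> str:
        lines = [
            "Bliss independence synergy"
            f" (perturbation: {self.model.perturbation},"
            f" reference: {self.model.reference_line})",
            f"replicate mode: {self.model.replicate_mode},"
            f" AUC method: {self.model.auc_method}",
            "",
        ]
        cols = ["drug", "window", "fa", "fb", "expected", "observed",
                "excess", "excess_relative", "p", "n"]
        lines.append(
            self.records[cols].to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
        return "\n".join(lines)
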