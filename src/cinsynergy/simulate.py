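"""Synthetic confluency screens with known ground truth.

The generator emulates a plate-based proliferation screen on an adherent
cell line panel: logistic growth toward a 100% carrying capacity, a
genotype-specific proliferation penalty, multiplicative drug inhibition of
the growth rate, an optional extra rate reduction injected only into
combination wells (the mechanistic handle for a Bliss-excess interaction),
a 1:8 passage on a configurable day, 2-hour or daily sampling, a 3x3
biological-by-technical replicate layout, and multiplicative lognormal
measurement noise.

Because the interaction is injected on the growth rate while synergy is
read out on AUC-derived fractional inhibitions, the generator also computes
the *realized* AUC-scale Bliss excess from the noiseless curves; that value
— not the injected rate factor — is the ground truth a recovery analysis
must reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .growth import WellSeries
from .synergy import expected_inhibition, fractional_inhibition

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Condition",
    "simulate_logistic_curve",
    "apply_noise_and_passage",
    "simulate_screen",
    "default_design",
    "calibrate_bliss_excess_rate",
]


@dataclass(frozen=True)
class Condition:
    """A (cell line, drug, dose) combination."""

    cell_line: str
    drug: str
    dose_um: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a synthetic screen.

    Defaults mirror an 8-day live-cell imaging screen: ~23 h doubling time
    for the unperturbed line, seeding at 2% confluency, monitoring every
    2 h, a 1:8 passage on day 4, three technical replicates in each of
    three biological replicates, and 5% multiplicative measurement noise.
    """

    r_base: float = 0.03  # per hour (~23 h doubling)
    K: float = 100.0  # carrying capacity, percent confluency
    c0: float = 2.0  # seeding confluency, percent
    genotype_penalty: Mapping[str, float] = field(
        default_factory=lambda: {"RPE1": 1.0, "RPE1_Mad2cKD": 0.75}
    )
    drug_effect: Mapping[str, float] = field(
        default_factory=lambda: {"DMSO": 1.0, "drugA": 0.8}
    )
    drug_dose_um: Mapping[str, float] = field(default_factory=dict)
    #: scalar applied to every combination well, or a per-drug mapping
    bliss_excess_rate: float | Mapping[str, float] = 0.0
    noise_cv: float = 0.05
    cadence_h: float = 2.0
    duration_h: float = 192.0
    passage_day: float | None = 4.0
    split_ratio: float = 8.0
    n_bio: int = 3
    n_tech: int = 3
    bio_rate_cv: float = 0.0
    seed: int = 0
    vehicle: str = "DMSO"
    reference_line: str = "RPE1"

    def __post_init__(self) -> None:
        if not (0 < self.c0 < self.K):
            raise ConfigError("seeding confluency must satisfy 0 < c0 < K")
        if self.r_base <= 0:
            raise ConfigError("r_base must be positive")
        for name, f in {**self.genotype_penalty, **self.drug_effect}.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"multiplicative factor for {name!r} not in [0, 1]")
        rates = (
            self.bliss_excess_rate.values()
            if isinstance(self.bliss_excess_rate, Mapping)
            else [self.bliss_excess_rate]
        )
        if any(r < 0 for r in rates):
            raise ConfigError("bliss_excess_rate must be >= 0")
        if self.cadence_h <= 0 or self.duration_h <= 0:
            raise ConfigError("cadence_h and duration_h must be positive")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ConfigError("n_bio and n_tech must be >= 1")
        if self.noise_cv < 0 or self.bio_rate_cv < 0:
            raise ConfigError("coefficients of variation must be >= 0")
        if self.split_ratio < 1:
            raise ConfigError("split_ratio must be >= 1")
        if self.passage_day is not None:
            tp = self.passage_day * 24.0
            if not (0 < tp < self.duration_h):
                raise ConfigError("passage time lies outside the screen duration")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 0.5 * self.cadence_h, self.cadence_h)

    @property
    def passage_time_h(self) -> float | None:
        return None if self.passage_day is None else self.passage_day * 24.0

    def is_combination(self, condition: Condition) -> bool:
        return (
            condition.cell_line != self.reference_line
            and condition.drug != self.vehicle
        )

    def effective_rate(self, condition: Condition) -> float:
        """r_eff = r_base x genotype penalty x drug effect x interaction."""
        try:
            g = self.genotype_penalty[condition.cell_line]
        except KeyError:
            raise ConfigError(f"no genotype penalty for {condition.cell_line!r}")
        try:
            d = self.drug_effect[condition.drug]
        except KeyError:
            raise ConfigError(f"no drug effect for {condition.drug!r}")
        r = self.r_base * g * d
        if self.is_combination(condition):
            if isinstance(self.bliss_excess_rate, Mapping):
                r *= 1.0 - self.bliss_excess_rate.get(condition.drug, 0.0)
            else:
                r *= 1.0 - self.bliss_excess_rate
        return r


@dataclass
class GroundTruth:
    """Noiseless per-condition AUCs and the realized Bliss quantities.

    ``conditions`` has one row per (cell_line, drug, dose) with the
    effective rate and noiseless sum-AUC; ``synergy`` has one row per
    combination condition with Fa, Fb, expected and observed inhibition,
    excess (observed - expected) and relative excess (excess/expected).
    """

    conditions: pd.DataFrame
    synergy: pd.DataFrame


def _logistic(t: np.ndarray, c0: float, r: float, K: float) -> np.ndarray:
    return K / (1.0 + ((K - c0) / c0) * np.exp(-r * t))


def _noiseless_curve(config: SimConfig, r_eff: float, passage: bool = True) -> np.ndarray:
    """Closed-form logistic samples, with the passage dilution if configured.

    At the passage time the logistic state is divided by the split ratio and
    growth restarts from the diluted confluency.
    """
    t = config.times
    c = _logistic(t, config.c0, r_eff, config.K)
    tp = config.passage_time_h
    if passage and tp is not None:
        cp = _logistic(np.array([tp]), config.c0, r_eff, config.K)[0] / config.split_ratio
        late = t >= tp
        c = c.copy()
        c[late] = _logistic(t[late] - tp, cp, r_eff, config.K)
    return c


def simulate_logistic_curve(
    config: SimConfig, condition: Condition, rate_multiplier: float = 1.0
) -> WellSeries:
    """Noiseless logistic growth for one condition (no passage, no noise).

    Samples C(t) = K / (1 + ((K - c0)/c0) e^(-r_eff t)) at the configured
    cadence, where r_eff folds in the genotype penalty, the drug effect and
    (for combination wells) the injected interaction.
    """
    r_eff = config.effective_rate(condition) * rate_multiplier
    c = _logistic(config.times, config.c0, r_eff, config.K)
    return WellSeries(
        times=config.times,
        confluency=c,
        cell_line=condition.cell_line,
        drug=condition.drug,
        dose_um=condition.dose_um,
    )


def apply_noise_and_passage(
    series: WellSeries,
    config: SimConfig,
    rng: np.random.Generator,
    rate_multiplier: float = 1.0,
) -> WellSeries:
    """Apply the passage dilution and multiplicative measurement noise.

    The passage divides the logistic state by the split ratio at the passage
    time; growth then continues from the diluted state at the same effective
    rate.  Each observation is multiplied by lognormal noise with unit mean
    and coefficient of variation ``noise_cv``; values are clipped to
    [0, K].  Deterministic given the generator state.
    """
    r_eff = config.effective_rate(
        Condition(series.cell_line, series.drug, series.dose_um)
    ) * rate_multiplier
    c = _passaged_from(series, config, r_eff)
    c = _noisy(c[None, :], config, rng)[0]
    return series.replace_values(c)


def _passaged_from(series: WellSeries, config: SimConfig, r_eff: float) -> np.ndarray:
    tp = config.passage_time_h
    c = series.confluency.copy()
    if tp is None:
        return c
    if tp >= series.times[-1] or tp <= series.times[0]:
        raise ConfigError("passage time lies outside the observed duration")
    cp = _logistic(np.array([tp]), config.c0, r_eff, config.K)[0] / config.split_ratio
    late = series.times >= tp
    c[late] = _logistic(series.times[late] - tp, cp, r_eff, config.K)
    return c


def _noisy(values: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_cv == 0:
        return np.clip(values, 0.0, config.K)
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
    return np.clip(values * noise, 0.0, config.K)


def default_design(config: SimConfig) -> list[Condition]:
    """Full crossing of the configured cell lines and drugs."""
    return [
        Condition(line, drug, config.drug_dose_um.get(drug, 0.0))
        for line in config.genotype_penalty
        for drug in config.drug_effect
    ]


def _validate_design(design: Sequence[Condition], config: SimConfig) -> None:
    lines = {c.cell_line for c in design}
    with_vehicle = {c.cell_line for c in design if c.drug == config.vehicle}
    missing = lines - with_vehicle
    if missing:
        raise DesignError(
            f"no {config.vehicle!r} control condition for cell line(s): "
            + ", ".join(sorted(missing))
        )


def _well_labels(n_wells_per_bio: int, bio: int) -> tuple[list[str], list[str]]:
    """96-well plate/well names for one biological replicate."""
    rows = "ABCDEFGH"
    plates, wells = [], []
    for i in range(n_wells_per_bio):
        plate_idx, pos = divmod(i, 96)
        plates.append(f"B{bio}P{plate_idx + 1}")
        wells.append(f"{rows[pos // 12]}{pos % 12 + 1:02d}")
    return plates, wells


def ground_truth(design: Sequence[Condition], config: SimConfig) -> GroundTruth:
    """Noiseless AUCs and realized Bliss quantities for a design.

    Fractional inhibitions use the same sum-over-time-points AUC definition
    as the analysis pipeline, computed on the noiseless (passaged) curves.
    """
    _validate_design(design, config)
    rows = []
    auc_by_cond: dict[tuple[str, str], float] = {}
    for cond in design:
        r_eff = config.effective_rate(cond)
        auc = float(_noiseless_curve(config, r_eff).sum())
        auc_by_cond[(cond.cell_line, cond.drug)] = auc
        rows.append(
            {
                "cell_line": cond.cell_line,
                "drug": cond.drug,
                "dose_um": cond.dose_um,
                "r_eff": r_eff,
                "auc_noiseless": auc,
            }
        )
    conditions = pd.DataFrame(rows)

    ref = config.reference_line
    veh = config.vehicle
    auc_ref = auc_by_cond.get((ref, veh))
    syn_rows = []
    for cond in design:
        if not config.is_combination(cond):
            continue
        needed = [(ref, cond.drug), (cond.cell_line, veh), (ref, veh)]
        if any(k not in auc_by_cond for k in needed):
            continue
        fa = fractional_inhibition(auc_by_cond[(ref, cond.drug)], auc_ref)
        fb = fractional_inhibition(auc_by_cond[(cond.cell_line, veh)], auc_ref)
        observed = fractional_inhibition(
            auc_by_cond[(cond.cell_line, cond.drug)], auc_ref
        )
        expected = expected_inhibition(fa, fb)
        syn_rows.append(
            {
                "cell_line": cond.cell_line,
                "drug": cond.drug,
                "dose_um": cond.dose_um,
                "fa": fa,
                "fb": fb,
                "expected": expected,
                "observed": observed,
                "excess": observed - expected,
                "excess_relative": (observed - expected) / expected
                if expected != 0
                else np.nan,
            }
        )
    synergy = pd.DataFrame(
        syn_rows,
        columns=[
            "cell_line",
            "drug",
            "dose_um",
            "fa",
            "fb",
            "expected",
            "observed",
            "excess",
            "excess_relative",
        ],
    )
    return GroundTruth(conditions=conditions, synergy=synergy)


def simulate_screen(
    design: Sequence[Condition] | None = None,
    config: SimConfig = SimConfig(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full replicated screen.

    Returns a tidy long-format table (plate, well, cell_line, drug,
    dose_um, bio_rep, tech_rep, time_h, confluency_pct) and the
    :class:`GroundTruth` computed from the noiseless curves.  Technical
    replicates within a biological replicate share one latent rate
    multiplier, drawn with coefficient of variation ``bio_rate_cv`` (zero by
    default).  All randomness flows from ``config.seed``.
    """
    if design is None:
        design = default_design(config)
    _validate_design(design, config)
    gt = ground_truth(design, config)
    rng = np.random.default_rng(config.seed)

    t = config.times
    n_cond, n_bio, n_tech, n_t = len(design), config.n_bio, config.n_tech, t.size
    rates = np.array([config.effective_rate(c) for c in design])

    if config.bio_rate_cv > 0:
        sigma = math.sqrt(math.log1p(config.bio_rate_cv**2))
        bio_mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_bio)
    else:
        bio_mult = np.ones(n_bio)

    # noiseless curves per (condition, bio): shape (n_cond, n_bio, n_t)
    r = rates[:, None] * bio_mult[None, :]
    curves = _logistic(t[None, None, :], config.c0, r[:, :, None], config.K)
    tp = config.passage_time_h
    if tp is not None:
        cp = _logistic(np.array([[tp]]), config.c0, r, config.K) / config.split_ratio
        late = t >= tp
        curves[:, :, late] = _logistic(
            (t[late] - tp)[None, None, :], cp[:, :, None], r[:, :, None], config.K
        )

    # expand technical replicates and add measurement noise
    wells = np.broadcast_to(
        curves[:, :, None, :], (n_cond, n_bio, n_tech, n_t)
    ).reshape(-1, n_t)
    noisy = _noisy(wells, config, rng)

    cond_idx = np.repeat(np.arange(n_cond), n_bio * n_tech * n_t)
    bio_idx = np.tile(np.repeat(np.arange(n_bio), n_tech * n_t), n_cond)
    tech_idx = np.tile(np.repeat(np.arange(n_tech), n_t), n_cond * n_bio)

    cells = np.array([c.cell_line for c in design], dtype=object)
    drugs = np.array([c.drug for c in design], dtype=object)
    doses = np.array([c.dose_um for c in design])

    # well positions: within a biological replicate, wells are laid out
    # condition-major across as many 96-well plates as needed
    n_wpb = n_cond * n_tech
    plate_names = np.empty((n_bio, n_wpb), dtype=object)
    well_names = np.empty((n_bio, n_wpb), dtype=object)
    for b in range(n_bio):
        p, w = _well_labels(n_wpb, b + 1)
        plate_names[b, :] = p
        well_names[b, :] = w
    # map (cond, bio, tech) -> well serial within bio = cond * n_tech + tech
    well_serial = cond_idx * n_tech + tech_idx

    table = pd.DataFrame(
        {
            "plate": plate_names[bio_idx, well_serial],
            "well": well_names[bio_idx, well_serial],
            "cell_line": cells[cond_idx],
            "drug": drugs[cond_idx],
            "dose_um": doses[cond_idx],
            "bio_rep": bio_idx + 1,
            "tech_rep": tech_idx + 1,
            "time_h": np.tile(t, n_cond * n_bio * n_tech),
            "confluency_pct": noisy.reshape(-1),
        }
    )
    return table, gt


def calibrate_bliss_excess_rate(
    config: SimConfig,
    condition: Condition,
    target_excess: float,
    rate_bounds: tuple[float, float] = (0.0, 0.95),
) -> SimConfig:
    """Find the injected rate reduction realizing a target AUC-scale excess.

    Because the interaction acts on the growth rate while the ground-truth
    excess is defined on AUC-derived inhibitions, the mapping between the
    two is solved numerically (bisection on the noiseless ground truth).
    Returns a config whose realized excess for *condition* matches
    ``target_excess``.
    """
    from scipy.optimize import brentq

    design = default_design(config)

    def realized(rate: float) -> float:
        cfg = replace(config, bliss_excess_rate=rate)
        syn = ground_truth(design, cfg).synergy
        row = syn[(syn["cell_line"] == condition.cell_line) & (syn["drug"] == condition.drug)]
        return float(row["excess"].iloc[0])

    lo, hi = rate_bounds
    f_lo = realized(lo) - target_excess
    if abs(f_lo) < 1e-12:
        return replace(config, bliss_excess_rate=lo)
    if f_lo > 0:
        raise ConfigError(
            "target excess below the additive-null baseline; cannot calibrate "
            "with a non-negative injected rate reduction"
        )
    rate = brentq(lambda x: realized(x) - target_excess, lo, hi, xtol=1e-10)
    return replace(config, bliss_excess_rate=float(rate))
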