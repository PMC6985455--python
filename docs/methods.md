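# Methods

## Scope and model

`cinsynergy` quantifies plate-based proliferation screens in which two cell
lines — an unperturbed reference and a perturbed line (for example a
doxycycline-induced spindle-checkpoint knockdown, or a stable trisomic
derivative) — are exposed to a drug panel, and asks two questions:

1. **Differential sensitivity** — for which drugs does the perturbed line
   respond differently from the reference, after correcting each line for
   its own baseline growth?
2. **Synergy** — where a difference exists, is the combined effect of drug
   and perturbation larger than the Bliss-independence expectation?

The raw observable is confluency (percent of the culture surface covered)
sampled over time per well, as produced by live-cell imagers or by
image-segmentation tools; the package starts from these tidy tables and
never touches images.

## Growth summaries

**AUC.** The default cumulative-growth readout is the *sum of confluencies
over time points*, the natural convention when every well shares one
evenly spaced grid. A trapezoid integral (percent·hours) is available for
unequal grids; on a logistic curve sampled every 2 h it agrees with
adaptive quadrature of the closed form to well under 0.5%.

**Exponential cutoff.** Proliferation rate is summarised by the slope of
log-linear growth, which requires deciding where exponential growth ends.
The rule: starting at the first positive observation, fit an ordinary
least-squares line to (time, ln confluency) over every expanding window and
return the largest end time whose window still reaches R² ≥ `r2_min`
(default 0.99, minimum 4 points). The rule is deliberately simple,
deterministic and configurable; if no window qualifies the earliest full
window is returned flagged `low_quality`. The cutoff is detected once per
condition on the replicate-mean curve and shared between a drug and its
vehicle control, so that the slope ratio reduces to a confluency ratio at
the cutoff.

**Slopes.** Two conventions are provided. `slope_relative` is
C_drug(t*)/mean C_control(t*) at the shared cutoff t*. `slope_manual` is
−ln(C/100)/t_days — implemented literally, including its counter-intuitive
property of *decreasing* as confluency rises; we do not second-guess the
intent, and natural log on the confluency *fraction* is used (the log base
cancels in control-relative ratios only when both terms share it, so the
choice is fixed and documented rather than configurable per call).

**Control normalization.** `normalize_to_control` divides each well's
metric by the mean of the matching vehicle wells, by default pooled per
cell line (one control mean per line). A per-biological-replicate scope is
also provided and is the default inside the differential model — see below.

**Windows.** Screens with a passage (1:8 split on day 4 by default) are
analysed per window (e.g. days 1–4 and days 5–8) rather than stitching a
cumulative curve; windows are half-open so each sample belongs to exactly
one window, which makes sum-AUCs exactly additive. For trapezoid AUCs an
`edges="shared"` mode duplicates boundary samples into both windows so the
window integrals add up to the full integral; a stitched-cumulative mode
(post-passage values multiplied by the split ratio) exists behind
`stitch_passage`.

## Differential sensitivity

For each drug, control-relative metrics of the two lines are compared with
a t-test; the effect is log2(mean_A/mean_B) and p-values are
Bonferroni-corrected (`p_adj = min(1, m·p)`, family size defaulting to the
number of drugs tested but overridable to the designed panel size). Hits
satisfy |effect| ≥ `effect_min` and corrected p < α.

Choices that were genuinely open, and what we chose:

* **Test variant.** Welch's unequal-variance t-test by default, pooled
  Student's as an option. Welch is known to be conservative below ~6
  observations per group (measured rejection ≈0.032 at n = 3 per group,
  ≈0.049 at n = 9, α = 0.05); calibration checks therefore run at 9 per
  group, where the approximation holds.
* **Replicate unit.** Technical replicates are not independent; by default
  they are averaged within each biological replicate and the biological
  replicate is the unit (`replicate_unit="bio"`). Treating all 9 wells as
  independent is available (`"well"`).
* **Normalization scope.** Dividing every well of a line by one pooled
  control mean makes all of that line's values share a random
  denominator; the resulting correlation is invisible to a t-test on the
  normalized values and roughly doubles the variance of the mean ratio,
  inflating type-I error and destroying Bonferroni family-wise error
  control. The differential model therefore normalizes within each
  biological replicate by default (`normalize_per="bio_rep"`), which keeps
  replicate values independent and each marginal test calibrated —
  Bonferroni then controls family-wise error under arbitrary dependence.
  The pooled convention remains available (`normalize_per="cell_line"`)
  for exact reproduction of the classical procedure.

## Bliss synergy

Fractional growth inhibition is F = 1 − AUC(treated)/AUC(reference), with
the reference being the unperturbed line under vehicle. For drug a and
perturbation b the Bliss expectation is Fa + Fb − Fa·Fb; the synergy
signal is excess = observed − expected. Both the absolute excess
(×100 = percentage points of inhibition) and the relative excess
(excess/expected; "X% stronger than additive") are always reported, since
published synergy percentages are quoted in both conventions. Negative Fa
or Fb (growth stimulation) are clipped to zero *inside* the Bliss formula
only and flagged, never altered in reports.

**Significance.** Three replicate modes:

* `"well"` (default): each combination well's AUC against the mean
  reference AUC gives a replicate-level observed inhibition; a one-sample
  t-test compares these to the expectation built from mean Fa and mean Fb.
  This is the conventional construction, but it treats the expectation as
  known although Fa, Fb and the reference mean carry sampling noise of the
  same order as the combination wells. End-to-end on null screens
  (3×3 wells per group, 5% noise) its rejection rate at α = 0.05 is ≈0.3 —
  use it for point estimates and for comparability, not for calibrated
  error rates.
* `"paired"`: wells are matched across the four condition groups by
  (biological, technical) replicate; each matched set yields its own
  excess, tested against zero. This propagates all four groups' noise and
  is calibrated (measured ≈0.05–0.07 end to end).
* `"bootstrap"`: percentile p-value from resampling wells within each of
  the four groups.

The one-sample test itself is exactly calibrated when the expectation is
known (rejection 0.046–0.05 over 2,000 null simulations); the inflation in
`"well"` mode is purely the plug-in expectation.

**Windowed synergy** re-computes all four groups' AUCs inside each day
window, each window with its own reference.

## Synthetic screens and ground truth

The generator emulates the screen the analysis is designed for:

* logistic growth C(t) = K/(1 + ((K − c0)/c0)e^(−r_eff t)) toward a 100%
  carrying capacity; seeding at c0 = 2% (≈1,600 cells in a 96-well);
  r_base = 0.03 h⁻¹ (≈23 h doubling);
* multiplicative structure r_eff = r_base × genotype penalty × drug
  effect, with a 25% penalty for the checkpoint-knockdown line by default;
* an optional extra rate reduction only in combination wells — the
  mechanistic handle that creates a Bliss interaction;
* a 1:8 passage on day 4 modelled as an instantaneous division of the
  logistic state, after which growth continues from the diluted state;
* 2-h sampling over 8 days; 3 biological × 3 technical replicates, with
  technical replicates sharing a biological replicate's latent rate
  (between-replicate rate CV configurable, 0 by default);
* multiplicative lognormal measurement noise with unit mean; the noise CV
  of confluency estimation is not documented for the imaging systems this
  emulates, so it is a first-class, always-reported parameter
  (default 0.05), and values are clipped to [0, K].

**Ground truth on the AUC scale.** The interaction is injected on the
growth *rate*, but synergy is read out on AUC-derived inhibitions, and a
multiplicative rate null is *not* exactly Bliss-additive on the AUC scale:
for exponential-phase growth the map rate → AUC is log-convex in log-rate,
so a pure rate product gives slightly *negative* AUC-scale excess (≈−0.02
to −0.04 at the default effect sizes). The generator therefore computes
the *realized* excess from the noiseless curves — that is the ground truth
recovery is judged against — and `calibrate_bliss_excess_rate` inverts the
rate→excess map numerically (Brent bisection) when an exact target excess
(including an exact additive null) is wanted.

**Recovery study conditions.** The parameter-recovery experiment scans
true excess over {0, 0.05, 0.15, 0.30} at 3×3 replicates and 5% noise.
Its single-agent effects are moderate (drug effect 0.9, genotype penalty
0.85, giving Fa ≈ 0.24 and Fb ≈ 0.33): with the default strong effects the
expected inhibition is ≈0.71 and an excess of 0.30 would push the required
observed inhibition past complete inhibition — infeasible by construction,
not by estimation. Measured recovery error is ≤0.002 across the grid;
additive-null bias at 100 wells per group is <10⁻³.

**What the generator does not emulate.** Spatial plate effects, edge
wells, drug decay between medium refreshes, density-dependent drug
potency, cell death as an explicit process (death is folded into the net
rate), heteroscedastic segmentation error at very low confluency, and
day-to-day imager drift. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to all real-plate artefacts.

## Cell-level statistics

* **Phenotype counts**: Pearson chi-squared without continuity correction
  by default (the typical 2×k tables have moderate n; Yates is an option);
  zero marginals are errors, expected counts <5 warn. Note p is *not*
  invariant to scaling all counts: proportions fixed, statistic grows
  linearly with n (documented and tested).
* **Proportions** (e.g. aneuploid-cell fractions from single-cell
  sequencing): percentage with a Wilson 95% interval; display value
  rounded to the nearest integer.
* **Track speeds**: Wilcoxon–Mann–Whitney, exact enumeration up to a
  combined n of 12 without ties, normal approximation with tie correction
  otherwise. Exact and asymptotic p agree to ≈0.005 in the median at the
  crossover (worst case ≈0.015 in the tails). Tracks are pooled across
  movies, mirroring common practice; pooling ignores movie-level
  clustering, so p-values are optimistic when movies differ systematically.
* **MT assembly rates**: the cell is the unit — the default 20 per-MT
  measurements are averaged within each cell before an unpaired two-sided
  t-test; individual MTs are never treated as independent.
* **Mitotic timing**: prophase→metaphase and anaphase→de-condensation
  durations from per-cell timestamps; unordered records are rejected with
  a reason; groups compared by rank-sum (default) or Welch t.

## Numerical and reproducibility choices

* All randomness flows from one integer seed per run; simulated tables are
  reproducible bit for bit and pipeline outputs byte for byte.
* Expanding-window R² uses cumulative sums (O(n)); zero-variance windows
  (flat series) count as perfect fits.
* Nearest-sampled-time matching breaks ties toward the earlier time point.
* Degenerate inputs never produce silent NaNs: zero-variance comparisons
  return flagged conventional p-values (1 on equality, 0 otherwise),
  missing condition groups and missing vehicle controls raise errors
  naming the offender.
* Result CSVs carry `#` header comments naming the producing stage and a
  SHA-256-derived hash of the configuration.

## Problem sizes used in the shipped checks

Calibration checks use 2,000 null simulations per t-test; family-wise
error uses 300 simulated 95-drug null screens of 4 days at 2-h cadence;
null-bias uses 10 screens of 100 wells per condition. These sizes give
Monte-Carlo standard errors comfortably below the decision margins
(±0.015 on type-I rates, 0.02 slack on family-wise error).

## Known limitations

* The published screens' synergy percentages can only be re-derived from
  the deposited supplementary growth-curve tables, which are not
  redistributed here; the corresponding benchmarks fail until those files
  are converted to the tidy CSV layout and placed under
  `data/supplementary/`.
* The `"well"` synergy test reproduces the conventional construction but
  is anticonservative (see above); calibrated inference should use
  `"paired"` or `"bootstrap"`.
* The sum-AUC convention requires one shared time grid; mixed-cadence
  screens must use the trapezoid method.
* Dose–response (Hill) modelling, Loewe/HSA/ZIP synergy surfaces, image
  segmentation and particle tracking are out of scope by design.
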