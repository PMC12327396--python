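# Methods

## Problem setting

After repeated extra-label dosing of a drug to a lactating animal, residues
deplete from milk roughly log-linearly once absorption and distribution are
complete.  A withdrawal interval (WDI) is a statement about that depletion:
the time after the last dose at which milk residues can be declared safe
with respect to a regulatory ceiling.  The package implements the
estimation chain from raw concentration–time records to the WDI, with a
synthetic data generator standing in for raw study data that residue
studies rarely publish.

All concentrations are handled in ng/mL, times in hours on the study clock
(first dose = 0 h), doses in mg/kg; areas under the curve are reported in
h·μg/mL with a single explicit 10³ conversion.

## Data model and censoring

A study is a long-format table of records — animal, matrix (plasma or
milk), time, replicate, concentration, censoring state, provenance — plus a
dosing regimen (default 1 mg/kg every 24 h × 6), assay limits (LOD
4 ng/mL, LLOQ 15 ng/mL) and a 12 h milking grid.  The censoring rule maps a
true concentration c to: below-LOD (unreported) for c < LOD;
detected-but-not-quantifiable, value retained with a flag, for
LOD ≤ c < LLOQ; quantified otherwise.

Two different "usability" conventions are deliberate:

* **NCA** keeps detected-but-not-quantifiable values by default (they carry
  real information for terminal fits on sparse series; configurable).
* **The depletion regression** behind the tolerance-limit WDIs uses only
  quantified (≥ LLOQ) measurements, plus assigned (LOD-filled) and
  simulated values.  This is the convention the regulatory workflow
  implies: an animal's "terminal-phase time points" are counted as its
  quantifiable milkings from the post-last-dose peak onward, and the whole
  point of the LOD back-fill scenario is that sub-LLOQ milkings do not
  count.

## Non-compartmental analysis

Per animal and matrix the engine estimates the standard set: observed
Cmax/Tmax; the terminal elimination rate λz by ordinary least squares of
ln C on t over the best suffix of post-peak points (k ≥ 3, the observed
Cmax point excluded, adjusted R² maximised, ties to the larger set — the
convention of the commercial NCA tools; a short first-dose window may fall
back to admitting the Cmax point); T½ = ln 2 / λz; linear-trapezoid AUC
over a dosing interval and to infinity (tail C_last/λz, with the
percentage extrapolated reported); MRT from the first-moment curve with
full tail terms C_last·t_last/λz + C_last/λz²; CL/F = dose/AUC∞;
Vd/F = CL/F ÷ λz; and the accumulation ratio
Rac = AUC(0–τ, last dose)/AUC(0–τ, first dose).  Milk gets the observed
Cmax/Tmax (reported on the post-last-dose clock) and the theoretical
terminal half-life and AUC(last dose → ∞), plus the per-animal
milk-to-plasma AUC ratio.  Parameters are summarised as geometric means,
geometric SDs (exp of the n−1 SD of logs) and ranges; the GSD is undefined
for n = 1 and is reported as such.

## WDI estimators

**Half-life method.** WDI = 10 × terminal milk half-life; after ten
half-lives less than 2⁻¹⁰ ≈ 0.1% of residue remains.

**Tolerance-limit methods.** All animals and replicates pool into one OLS
regression of log concentration on time after the last dose (observations
treated as i.i.d. given time — the homogeneous-population assumption of the
regulatory framework; a per-animal-mean option exists for sensitivity
analysis).  The upper one-sided tolerance limit at time t is

    U(t) = yhat(t) + K(t) * s,
    K(t) = d(t) * nct_ppf(gamma, n - 2, z_p / d(t)),
    d(t) = sqrt(1/n + (t - tbar)^2 / Sxx)

which covers the p-quantile of the response at t with confidence γ — an
exact pointwise property of the noncentral-t construction that the test
suite verifies by Monte Carlo (coverage 95% ± 1.5 points over 2,000
simulated regressions, and the classic n = 10 single-sample factor 3.981).
The FDA-style estimator uses p = 0.99, γ = 0.95 against the 4 ng/mL LOD
(zero-tolerance proxy) on log₁₀; the EMA-style estimator uses p = 0.95,
γ = 0.95 against the 15 ng/mL MRL on natural logs.  The log base is
cosmetic: the bound is affine in it, and the two agree to 0.01 h.

The WDI is the **latest** down-crossing of U(t) through log(tolerance),
found by a 0.25 h scan plus bisection to 0.01 h over a horizon extending
ten mean-line half-lives past the deterministic crossing (the bound can be
non-monotone far from t̄ because leverage grows, and the regulatory reading
requires the bound to be at-or-below tolerance from the WDI onward).  A
bound below tolerance everywhere gives WDI 0; a bound that never comes down
is reported as an explicit non-finite result, never a number.  Continuous
WDIs are rounded up to the next multiple of the milking interval.
Lack-of-fit and variance-homogeneity pre-tests are available as reported
diagnostics only; they never alter the estimate.  The minimum-data rule
(10 animals, triplicates, ≥ 4 terminal points per animal) is likewise a
recorded diagnostic rather than a hard error, because the augmentation
scenarios exist precisely to repair non-compliant datasets and must be able
to run on them.

## Monte Carlo augmentation scenarios

1. **LOD back-fill.** Any animal with fewer than four quantifiable terminal
   milk time points receives one record per replicate at the fill milking
   (default 166 h study clock = 46 h post last dose, the fourth milking
   counting from the 10 h peak) with concentration equal to the LOD and
   provenance `lod_filled`; the assignment replaces whatever unquantifiable
   measurement sat there.  Filling earlier than an animal's last
   quantifiable milking is an error.
2. **Virtual animals.** The cohort becomes the base animals (default: the
   five quantifiable at their fourth terminal point — the slower half)
   plus five virtual animals.  At each milk time point with at least two
   quantifiable base values, the base animal-means give a mean and CV and
   each virtual animal receives one draw (copied across the triplicate,
   with a per-replicate-draw option) from a lognormal parameterised to
   that mean and CV exactly (a zero-truncated normal is available); draws
   pass through the censoring rule.  Because the quantifiable subset at
   late times is the slow tail, virtual animals inherit its survivor bias.
3. **Simulated replicates.** Milk is restricted to Replicate A and two
   replicates (`simulated_repB`, `simulated_repC`) are regenerated per
   animal/time with mean equal to the Replicate-A value and CV equal to the
   pooled Replicate-A CV (root-mean-square of the across-animal CV at each
   terminal time point; a fixed analytical-CV override exists).  Draws are
   mean-corrected lognormal, so each animal/time expectation equals the
   Replicate-A value; below-LOD points stay below LOD.

All scenarios are pure functions of (dataset, options, seed) and mark every
added record's provenance.

## Synthetic study generator

Plasma follows a one-compartment model with first-order absorption,
superposed over doses:

    C(t) = sum_d  D*ka / (V/F * (ka - ke)) * (e^{-ke (t-t_d)} - e^{-ka (t-t_d)})

Milk is a first-order sub-compartment driven by plasma,
dCm/dt = k_in·Cp(t−lag) − k_out·Cm with k_in = mp·k_out, evaluated in
closed form.  Because k_out > ke, the milk terminal slope parallels the
plasma slope, and milk/plasma AUC equals the partition scale mp exactly —
the two structural features the downstream analysis assumes.

Defaults (geometric means, lognormal inter-animal variability):

| parameter | default | units | rationale |
|---|---|---|---|
| ka | 0.30 | 1/h | post-dose plasma Tmax ≈ 5.7 h, as reported in the emulated study |
| ke | ln 2 / 7.2 | 1/h | between the study's plasma (7.64 h) and milk (6.96 h) half-lives — one rate serves both matrices — and reproduces its eligibility split (about half the cohort short of a fourth quantifiable terminal milk point) |
| V/F | 365 | mL/kg | CL/F = ke·V/F ≈ 33 mL/kg/h, the reported steady-state clearance scale |
| mp | 0.27 | – | the reported milk/plasma AUC ratio |
| k_out | 0.50 | 1/h | milk peaks at the 10 h milking and declines near-parallel to plasma from the first post-peak milking |
| IIV GSDs | 1.25 (ka), 1.20 (ke), 1.25 (V/F), 1.50 (mp) | – | echo the reported GSDs/ranges (plasma T½ GSD 1.20; milk Cmax range 0.26–1.00 μg/mL) |
| assay CV | 3% | – | the reported HPLC precision (2.4–3.3%) |

Sampling follows the emulated design: plasma at 0–24 h after the first dose
and 0–168 h after the sixth; milkings every 12 h from 10 h to 454 h
(placing the milking grid 10 h after the first dose reconciles the 12 h
interval with the universal 10 h post-dose milk Tmax).  Assay error is
multiplicative lognormal, independent per replicate (milk in triplicate,
plasma singly); everything is reproducible from one seed, and the true
per-animal parameters travel with the dataset for recovery tests.
`generate_matched_dataset` walks seeds until a cohort realises the
published 5-of-10 eligibility split, the configuration at which scenario
comparisons are meaningful.

**What the generator does not emulate.** Real milk depletion is mildly
biphasic (the published peak, fourth-point mean and terminal half-life are
not jointly consistent with a single exponential), milk is accumulated
between discrete milkings rather than sampled instantaneously, and level
and slope are correlated across animals.  A one-compartment generator
therefore yields a somewhat flatter pooled depletion regression — its
tolerance-limit WDIs on synthetic cohorts run some hours to tens of hours
longer than the study's 70.1 h even though the per-animal half-lives match
— and it makes the virtual-animal scenario's upward bias smaller and
noisier than the single published realisation (+12.7 h): across matched
replications the Scenario-2 minus Scenario-1 difference averages near +1 h
with an SD of about 7 h.  Passing tests therefore demonstrate the
estimators' statistical properties (coverage, monotonicity, invariances,
orderings) and desk-scale reproduction of the published summaries, not
absolute reproduction of regression WDIs whose raw inputs were never
published.

## Numerical choices and degenerate inputs

* Terminal fits require three post-peak points and a negative slope; an
  all-censored or too-short series raises a no-fit error naming the animal
  and matrix (the pipeline collects these per stage instead of aborting).
* AUC windows interpolate linearly to window ends inside the sampled span
  and refuse windows outside it; AUC additivity holds to machine precision.
* Equal absorption and elimination rates degenerate the oral closed form
  and are rejected; the driven-compartment response uses the t·e^{−kt}
  limit when rates coincide.
* The crossing search tolerance is 0.01 h; rounding up uses a 10⁻⁹ slack so
  exact multiples of the milking interval are not bumped upward.
* Lognormal mean/CV draws use σ² = ln(1 + CV²), μ = ln(mean) − σ²/2, so
  the arithmetic mean and CV are matched exactly and CV = 0 degenerates to
  the mean.

## Known limitations

* No tissue (muscle/liver/kidney) WDIs, no PBPK or disease-state effects,
  no Tobit/ML treatment of censored values beyond the three published
  augmentation scenarios — all out of scope by design.
* The pooled regression ignores within-animal correlation; the
  animal-mean pooling option is the provided sensitivity check.
* Bioavailability F is never separated from V and CL (no intravenous arm);
  all clearances and volumes are per fraction absorbed.
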