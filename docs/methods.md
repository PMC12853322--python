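# Methods

This note records the statistical conventions the package implements, the
choices made where conventions genuinely diverge, and what the synthetic
cohorts do and do not establish.

## Outcome definition

The primary outcome is death or delisting for clinical deterioration within
90 days of listing, treated as a time-to-event endpoint.  Transplant and
removal for other reasons right-censor at their own time; everyone else is
administratively censored at day 90.  "Within 90 days" is read inclusively
(an event on day 90 counts).  Transplant is deliberately *not* modelled as
a competing risk: the scores are meant to rank mortality risk in the
absence of transplant, so independent censoring is the intended estimand.
Zero-day records are shifted to 0.5 days so that product-limit and partial
likelihood machinery (which need strictly positive times) applies; this
affects no reported quantity.

## Score conventions

* **Units.** Records store creatinine/urea/bilirubin in mg/dL, sodium in
  mmol/L, albumin in g/dL.  The RFH-GFR equation is evaluated with
  creatinine in µmol/L (×88.4) and urea in mmol/L (×0.1665).  This is not
  cosmetic: with registry-mean inputs the equation produces the printed
  66–72 mL/min cohort means only under these units (mg/dL inputs give
  values ~25× too large).  An executable test pins this reconciliation.
* **Ascites factor 0.92.**  The original RFH-GFR multiplies by 0.92 in the
  presence of moderate–severe ascites.  Two published statements fix this
  constant — an 8% GFR reduction, and a ≈0.692-point score increase equal
  to 8.306·ln(1/0.92) — and the package tests both as identities.  The
  ascites-inclusive score is always the larger; removing ascites can only
  lower priority.
* **Floors and clamps.**  Bilirubin and INR are floored at 1.0 before the
  logarithm in GEMA (MELD-family convention, adopted because the original
  GEMA convention is not restated anywhere); the sodium correction clamps
  to [125, 140] for GEMA-Na and MELD-Na, and MELD 3.0 uses its published
  [125, 137] sodium and [1.5, 3.5] albumin clamps with creatinine capped at
  3 mg/dL (4 mg/dL in classic MELD).  No bound is applied to RFH-GFR itself
  before the logarithm.  No dialysis adjustment exists in the data model.
* **Integer points.**  Continuous scores are rounded half-up and clamped to
  the 6–40 ranking band.  Half-up rounding makes the bounded-reclassification
  property exact: since the continuous ascites effect lies in
  (0.43, 0.70), the integer effect is 0 or 1 for every fractional part,
  never 2 — a property swept over 10⁶ random patients in the tests.
* **Missing albumin** excludes a record from MELD 3.0 only; any other
  missing score input rejects the record (complete-case policy).

## Synthetic cohorts

The generator emulates three registry profiles (UK, Spain, Australia):
sex and age (truncated normal), creatinine/urea/bilirubin/INR as
log-normals (parameterised from the published mean±SD or median/IQR),
sodium and albumin as truncated normals, and the three-level ascites
prevalence.  A Gaussian copula couples creatinine–urea (ρ = 0.6) and
bilirubin–INR (ρ = 0.4); the registries publish no joint structure, so
these are package defaults chosen to give plausible mild positive
dependence, and they are configurable.

Events arrive from a constant per-day hazard over the 90-day window:

```
λ_i = baseline · exp(0.18 · (GEMA-Na_i − 15) + 0.10·[mild] + 0.25·[mod–severe] + frailty_i)
```

with frailty ~ N(0, 0.5²).  The exponential (rather than Weibull) form
reflects the short window and the absence of any published shape
information.  The score coefficient, ascites offsets and frailty SD are
package defaults chosen so that (i) cohort-level discrimination lands in
the realistic Hc ≈ 0.75–0.79 range, (ii) ascites adds risk on top of the
score (mirroring the reported score-adjusted hazard ratios in the 1.2–1.4
range), and (iii) event prevalence by ascites grade is strictly ordered
none < mild < moderate–severe.  Transplant is an independent exponential
clock; whichever of event, transplant and day-90 administrative censoring
comes first defines the record, with observed times rounded up to whole
days (producing the heavy ties real registries show).

`calibrate_profile` bisects the baseline hazard and transplant rate
(alternating, on a log scale, with common random numbers) until the
simulated 90-day outcome prevalence and transplant fraction hit the
registry targets; the shipped default configurations carry pre-calibrated
rates (e.g. UK: baseline 2.34×10⁻³/day, transplant 1.80×10⁻²/day), and the
test suite re-derives them from scratch.  One deliberate compression: the
published transplant fractions are whole-waitlist figures, but the
generator lives entirely on the 90-day window, so the same fraction is
reached within 90 days.  This preserves the censoring intensity that the
evaluation machinery faces at the 90-day horizon at the cost of a
faster-than-real organ supply.

What passing tests on these cohorts do **not** show: agreement with any
registry's numerical Hc values (the real data are not public), realistic
aetiology mix, longitudinal score updates after listing, or queueing
dynamics in organ allocation.

## Evaluation conventions

* **Harrell's c.**  A pair is usable when the shorter time belongs to an
  event; equal-time pairs are unusable unless both are events with tied
  scores (credited 0.5).  Score ties among usable pairs count 0.5.  The
  standard error is the degree-2 U-statistic ("structural components")
  estimate 4·var(q_i)/n from per-patient influence components — no
  resampling.  The estimator is verified against exhaustive pair
  enumeration on 500 random instances and against an independent library
  implementation on tie-free data.
* **Correlated c comparison.**  The difference of two c-indices computed on
  the same patients uses the paired influence components, so the
  covariance between the estimates is captured; the test statistic is
  normal.  Under an equal-information null (two equally noisy versions of
  one linear predictor, waitlist-like censoring) the measured type-I error
  at α = 0.05 is ≈ 0.044 over 2000 replicates at n = 500, and the variance
  agrees with the leave-one-out jackknife within 15%.  Identical score
  vectors report difference 0, variance 0, p = 1 by convention.
* **Brier score.**  Raw scores are mapped to 90-day event probabilities by
  a univariable proportional-hazards fit on the same data (the minimal
  monotone mapping; a score is a ranking, not a probability), then scored
  by the IPCW mean squared error at 90 days: events weight 1/G(T⁻),
  subjects under observation at the horizon weight 1/G(90⁻), earlier
  censorings contribute through the weights only, with G the product-limit
  censoring survival.
* **GND calibration.**  Deciles of predicted risk; per bin the observed
  90-day event probability is the product-limit estimate with Greenwood
  variance; χ² = Σ(obs − pred)²/var.  Bins with expected events < 2 — or
  with no observed events, whose variance is undefined — are merged into
  the adjacent bin with more expected events (ties toward the centre)
  until every bin qualifies; the merge trace and the decile→bin map are
  returned.  Degrees of freedom: the default reference is χ² with *one df
  per final bin*, because the predicted risks are externally supplied and
  no parameter is estimated on the validation data; simulation confirms
  this choice is calibrated (rejection ≈ 0.05) where the per-bin normal
  approximation holds, while the bins−1 convention used in registry
  reports (available as `df_convention="bins_minus_1"`) over-rejects by
  design.  A known limitation either way: at waitlist-like event sparsity
  (≈25–30 events per decile) the per-bin Wald z's are skewed and the test
  over-rejects regardless of df; the calibration null in the test suite
  therefore runs at adequate event density (~27% events, n = 5000), and
  GND results on sparse strata should be read qualitatively.
* **Decision curves.**  Net benefit at the 90-day horizon,
  NB(t) = P(risk ≥ t, event) − P(risk ≥ t, event-free)·t/(1−t), with both
  probabilities from the product-limit estimator inside the treated
  subset; treat-all and treat-none references included; thresholds with an
  empty treated subset report 0 and are flagged.
* **Reclassification.**  Integer-point cross-tabulation with row-normalised
  percentages (rows: first model), and downgraded/unchanged/upgraded
  groups by the sign of (second − first), each with its 90-day outcome and
  transplant percentages.

## Sample-size calculation

The design module answers: how many patients are needed to distinguish the
discrimination of two correlated prognostic models on right-censored data?
Discrimination is the Royston–Sauerbrei D, reachable from Harrell's c via
the published cubic D = 5.50(c−0.5) + 10.26(c−0.5)³.  The implemented
calculation takes the reference (established) model's SE(D) from its
validation cohort and works on the event scale with per-event variance

```
σ² = (π²/2) · SE_ref² / (1 − censoring proportion)
events = (z_{1−α/2} + z_{1−β})² · σ² / (D₁ − D₂)²
n = ceil(events / outcome prevalence);   events_required = floor(n · prevalence)
```

Among the variants of the cited discrimination-based methodology (which
differ in whether one or both SEs enter and in how censoring is treated),
this is the one that exactly reproduces the published design value for
this comparison (n = 4932 with 271 events under D₁ = 1.9244658,
SE = 0.2044043, D₂ = 1.79807867, power 90%, two-sided α = 0.05, censoring
50%, prevalence 5.5%), and that reproduction is an executable test.  The
candidate model's SE is carried in the inputs and the trace for reporting
but does not enter the variance; required n is therefore conservative in
the reference model's uncertainty and monotone in power, |ΔD| and SE_ref.
Equal D values return an explicit "undetectable difference" status.

## Problem sizes in the test suite

The stochastic suites run at sizes chosen to keep Monte-Carlo error well
inside the asserted bands: 2000 replicates at n = 500 for the comparison
test's type-I error, 2000 replicates at n = 5000 for the calibration null
(plus 100 replicates for power), 100 cohorts of n = 5000 for the
discrimination-ordering check, and a fresh n = 50 000 cohort for the
generator's registry calibration (targets ±0.5 pp on prevalence, ±2 pp on
transplant fraction).

## Known limitations

* Registry-reported Hc values cannot be reproduced without the registry
  data; the synthetic cohorts establish orderings and calibration
  properties, not published point estimates.
* The Cox, Kaplan–Meier and log-rank surfaces delegate to lifelines
  (Efron ties, Wald CIs); proportional-hazards diagnostics and competing
  risks are out of scope.
* The generator has no organ-supply dynamics; transplant intensity is a
  constant rate compressed into the 90-day window as described above.
* MELD-Na is computed unconditionally (no "MELD > 11" gate as in some
  allocation policies), matching how the score family is compared here.
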