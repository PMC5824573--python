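# Methods

## The model

`gdmburden` estimates the short-term (last pregnancy trimester, ~90 days)
economic burden of gestational diabetes mellitus (GDM) in Italy from the
national health-service perspective, comparing pregnancies complicated by
GDM with euglycemic (normal) pregnancies. The model has three layers:

1. **Antenatal outpatient costing.** Each resource item (OGTT, glucose
   test strips, finger sticks, insulin and consumables, obstetric visits
   and ultrasounds, a visual field test) carries a unit cost and a
   per-group consumption frequency. The cost per case of group *g* is

   Σ_i  c_i · n_i(g),

   where n_i(g) is the number of units consumed over the horizon. For
   frequencies given as a range ("every 3–4 weeks", "1–2 shots/day") the
   conservative lower bound is used: per-day ranges take the lower rate,
   and interval ranges take the widest interval, so an item every x–y
   weeks is consumed floor((horizon/7)/y) times. With a 90-day horizon
   this yields 6, 3 and 2 obstetric visits for the insulin-treated,
   diet-treated and euglycemic groups respectively. The GDM group's
   outpatient cost is the insulin-share-weighted mean of the diet- and
   insulin-treated costs (default share 14%).

2. **Inpatient probability tree.** Per group, the mother faces one chance
   node over the six delivery DRGs (370–375), each leaf carrying its
   LOS-adjusted tariff; the infant faces a macrosomia (birthweight ≥ 4 kg)
   chance node followed by a conditional outcome node over hypoglycemia,
   hyperbilirubinemia, shoulder dystocia, respiratory distress, brachial
   plexus injury, or normal newborn. Outcomes are treated as mutually
   exclusive and exhaustive, with the normal-newborn probability closing
   each conditional vector to one. Expected cost is the sum of
   probability × cost over leaves; `enumerate_tree` provides the explicit
   leaf listing as a brute-force cross-check of the closed-form sums.
   Delivery probabilities are stored as exact admission-count ratios
   (e.g. 4019/11434), not as rounded percentages, which is what lets the
   per-case tables reproduce to 0.1 €. Neonatal outcome costs are
   group-independent because the discharge database cannot attribute an
   infant to a GDM or euglycemic mother. No discounting is applied: the
   horizon is under a year.

3. **Burden scaling.** GDM cases = round(births × prevalence) (half-up;
   502,596 × 0.109 → 54,783 with the defaults). The annual burden is
   cases × (GDM − euglycemia total cost per case).

Money is carried at full floating precision and rounded only for
reporting, since the published per-case figures are rounded sums of
unrounded terms.

## Sensitivity analyses

**One-way (deterministic).** A named cost or probability is multiplied by
1 + δ (δ = ±0.2 by default) and the inpatient cost per case of both
groups is recomputed; outpatient costs are fixed tariff-list items and
are excluded. Perturbing a conditional outcome probability shifts the
normal-newborn complement by the opposite amount so the vector still sums
to one; a perturbation that pushes any probability outside [0, 1] (or the
complement below 0) is an error, not a silent clamp. The tornado ranking
orders parameters by the width of the induced range in the GDM −
euglycemia cost difference.

**Probabilistic (Monte Carlo).** Per iteration every probability and
inpatient cost is redrawn and both groups' expected inpatient costs are
recomputed (default 1000 iterations; vectorised over iterations):

- the delivery mix is drawn from a Dirichlet with the admission counts as
  concentration (each marginal is then the count-based beta), preserving
  the sum-to-one constraint that six independent betas would violate;
- probabilities known only as point values (the neonatal model) get
  moment-matched distributions with an assumed relative standard error of
  20% of the mean (config-exposed, `prob_se_frac`). Conditional outcome
  vectors default to a joint Dirichlet whose concentration is the median
  of the per-component moment-matched concentrations — a single Dirichlet
  cannot match all six component variances exactly, and the median makes
  the assumed dispersion representative rather than driven by one extreme
  component. An `independent` mode (betas + complement renormalisation)
  is available for comparison;
- costs are gamma with shape 1/cv² and scale mean·cv² (cv default 0.2),
  so every sampled quantity keeps its base-case mean.

Because all distributions are mean-preserving, the Monte Carlo mean
converges to the deterministic base case; the tests assert this at 10⁴
iterations within 1%. The published simulation *extremes* are not
reproduced: they depend on a distribution parameterization the source
tables do not pin down, so the package checks distributional properties
(seeded determinism, mean recovery, percentile ordering) instead. One
root seed drives a fixed draw order, so runs are bit-reproducible.

## Discharge-record extraction

The delivery side of the model can be re-estimated from administrative
discharge records:

- deliveries are mother-role admissions with DRG 370–375; other
  childbirth admissions are excluded and counted;
- a delivery is a GDM case if ICD9-CM 648.8 appears on the birth
  admission or on any admission of the same patient within a 90-day
  look-back window (matching the model horizon). Records lacking a
  patient ID cannot be linked and rely on the birth admission alone;
- the delivery mix is the per-group category counts normalised;
- per-stay costs: within each DRG category, admissions with LOS strictly
  above the category's 99th-percentile (nearest-rank on the sorted LOS;
  ties at the threshold retained) are dropped; the daily cost is the
  official tariff divided by the mean LOS of *all* remaining women in the
  category, and each group's cost is the daily cost times the group's
  mean LOS. The outlier filter is applied per category because the daily
  cost is computed per category;
- neonatal event costs are the mean tariff over infant admissions
  carrying the event's ICD9 code(s) in any diagnosis position
  (769; 775.0/775.6 pooled; 774.2/774.6 pooled; 767.6; 660.4); an event
  with no admissions is reported as missing, never as zero.

Neonatal outcome *probabilities* are never extracted: no code links an
infant to its mother, so they stay literature-derived.

## The synthetic cohort generator

No real discharge data can ship, so `synthetic_data` generates cohorts
with the structure the extraction assumes: Bernoulli GDM status at the
configured prevalence (default 10.9%), per-group multinomial delivery
DRG, integer LOS drawn as 1 + negative binomial (size 8 — overdispersed
with a genuine upper tail, so the 99th-percentile filter actually removes
records; only the LOS *means* enter the costing formula, so the family
choice is otherwise free), 9.1% of mothers without a patient ID, and a
quarter of GDM mothers coded only on a prior admission inside the
look-back window (the split between birth-record and look-back coding is
not documented anywhere; most coding plausibly happens at delivery).
Admission timing is an abstract day index. Infants carry at most one
complication code each (a categorical draw at the population-marginal
incidences implied by the outcome model), with tariffs drawn from a
unit-mean gamma (cv 0.2) around the configured event means — mutual
exclusivity mirrors the outcome model and keeps every extracted mean
unbiased.

`calibrated_cohort_spec` calibrates the generator to the packaged model:
the euglycemic mean LOS per DRG is fixed at plausible values (3–6 days,
caesarean longer than vaginal), and the GDM mean LOS and the tariff of
each category are solved (Brent root-finding on the analytic
negative-binomial trimmed means, with the outlier threshold computed on
the pooled group mixture) so that the *post-outlier-filter* LOS-adjusted
costing recovers the packaged per-stay costs exactly in expectation. The
generate → extract loop therefore differs from the model inputs only by
sampling noise: at 10⁵ mothers the dominant categories recover to well
under 1% and the expected mother inpatient cost per case to ~0.5%, while
intrinsically rare cells (DRG 374/375 in the GDM arm: order 10²
admissions) carry sampling errors of a few percent, which the tests bound
at three standard errors.

What the generator does **not** emulate: regional coding variation and
GDM under-reporting (real delivery records code GDM far below clinical
prevalence; a per-record code-dropout probability would be the natural
hook), mother–infant linkage, calendar seasonality, and demographic
covariates. Passing recovery tests therefore show the extraction logic is
correct under the stated sampling model, not that real administrative
data are unbiased.

## Numerical and interface choices

- Validation reports *all* violations (field + rule) rather than raising
  on the first; loading a config re-validates and refuses invalid sets.
- Configs are flat YAML mirroring the parameter structure; unknown keys
  are errors (typos must not silently fall back to defaults); partial
  configs merge over the packaged defaults; write → load round-trips.
- Problem sizes: property tests use 25 derandomised examples; Monte Carlo
  checks use 10⁴ iterations; recovery tests use cohorts of 2·10⁴ (module
  tests) and 10⁵ mothers (end-to-end), sizes at which binomial errors on
  the common categories are comfortably below the tolerances being
  asserted.
- The analysis scripts under `analysis/` are thin drivers; every
  computation they report lives in `src/gdmburden` and is unit-tested.

## Known limitations

- The cost perspective is the public payer only: no out-of-pocket
  spending, compliance effects, early (week 16–18) diagnosis pathway, or
  pre-delivery GDM-related admissions.
- DRG tariffs are a national proxy for cost; regional variation is out of
  scope (the sensitivity analyses are the instrument for tariff
  uncertainty).
- Long-term sequelae (maternal and offspring type 2 diabetes, obesity)
  are outside the 90-day horizon.
- The infant outcome probabilities come from a single large retrospective
  cohort; the model inherits whatever transportability limits that source
  has.
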