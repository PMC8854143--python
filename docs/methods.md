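# Methods

This note documents the models, conventions and numerical choices behind
`dietgap`, and what the synthetic-data tests do and do not establish.

## Disaggregation and classification

A record day is a list of (food code, grams consumed).  Recipes form a
directed acyclic graph of mass shares (shares > 0, summing to 1 within
1e-6); expansion distributes each product's mass over its components
recursively until only base ingredients remain, so total mass is
conserved exactly.  Duplicate entries of one food within a day are summed
before expansion.  Cycles are rejected at recipe-database construction;
a leaf code that is neither a recipe nor a mapped base ingredient raises
a lookup error naming the code and the child-day.

Each base ingredient maps to exactly one reference-diet group or to
`EXCLUDED`.  Classification rules, in order:

1. Energy (kcal/g × grams) accrues for *every* ingredient, including
   excluded ones — energy intake describes the whole diet, whereas the
   group totals only cover reference-diet foods.
2. Excluded ingredients contribute nothing else.  Sugary drinks are
   handled by recipe (water + sugar), so their sugar is counted while the
   water is not.
3. Any ingredient with sugar metadata contributes
   amount × total_sugar × f(sugar group) to `added_sugars`.  By default
   that mass is *also* retained in the source group (e.g. a sweetened
   yoghurt's full mass counts as dairy); the flag
   `subtract_added_sugar_from_source` removes it from the source first.
   The default reflects that published analyses do not state a
   subtraction; it makes `added_sugars` a partial double count by design.
4. Ingredients whose *primary* group is `added_sugars` (sugar, syrup)
   contribute only through the sugar estimate — never twice.
5. Form conversion (g raw/dry per g consumed) applies next; the identity
   is assumed where no factor is configured.
6. Dairy ingredients are multiplied by their category's milk-equivalent
   factor (milk 1.0, cream 2.7, cheese 5.0, butter 6.5; fermented liquids
   such as yoghurt and sour milk default to 1.0, overridable in the
   conversion config since published factor sets name only the four
   categories).  Butter therefore rides into the dairy group; lard,
   tallow and palm oil are mapped to `saturated_fats`.

Age split: each day is assigned by the child's decimal age on that day to
[3, 5) or [5, 7); days outside [3, 7) are dropped.  A child recorded on
both sides of the boundary contributes to both age groups, which are then
analyzed independently.

## Target scaling

Adult targets (g/day at 2500 kcal) are package constants; 16 rows
including the red-meat aggregate alongside its beef+lamb and pork
subgroups, each scaled independently.  Scaling multiplies every target
and range endpoint by mean energy / 2500 and rounds half away from zero
to integer grams — saturated fats to one decimal, matching the precision
used in published child-target tables.  Whole grains carry no range, so
range classification is skipped for that group.  Comparison semantics:
boundaries count as met, and range classification is inclusive at both
endpoints.  The diet gap is 100 × mean / target (percent of target).

## Usual-intake models

**Amount model** (whole grains, vegetables, fruits, dairy, unsaturated
oils, added sugars; also energy): Box-Cox transformed linear mixed model
with a person random intercept.  Covariates are an intercept,
completed-age-year dummies within the age group, a boy dummy and a
weekend (Sat/Sun) dummy; constant columns are dropped and rank-deficient
designs rejected.  Zeros (possible for nominally daily groups) are
handled by shifting all amounts by half the smallest positive value,
recorded in the fitted parameters.

For fixed λ the random-intercept LMM has an analytically profiled ML:
given the variance ratio r = σ²ᵤ/σ²ₑ, GLS gives β̂ and σ̂²ₑ in closed
form (V⁻¹ = I − r/(1+nᵢr)·J within person), leaving a one-dimensional
bounded search over log r (the r → 0 boundary is checked explicitly).
This exact fit agrees with statsmodels MixedLM to ~4 significant digits
(kept as a cross-check test) and is fast enough to sit inside the λ
profile.  λ is profiled over [0, 1] — a coarse 0.1-step pass then a
0.01-step refinement around the coarse optimum — maximizing the LMM
log-likelihood plus the Box-Cox Jacobian (λ−1)Σlog y.

**Correlated two-part model** (tubers, meats, poultry, eggs, fish,
legumes, nuts, saturated fats): a mixed logistic model for the
probability of consuming on a day and the amount model for consumed-day
amounts, with bivariate-normal person effects (u₁, u₂) correlated by ρ.
λ is profiled on the positive-day submodel and held fixed in the joint
fit; the joint likelihood integrates (u₁, u₂) on a covariance-scaled
two-dimensional Gauss–Hermite grid (13 nodes per axis; non-adaptive
scaling is accurate here because persons contribute at most five days,
keeping integrands smooth) and is maximized by L-BFGS-B over
(β_p, β_a, log σ₁, log σ₂, log σₑ, atanh ρ), initialized from a plain
logistic fit and the positive-day amount fit.  Degenerate regimes:

* all days positive → the probability part collapses to p = 1 and the
  amount model alone is returned;
* no positive day at all → explicit error;
* positive days but no person with two of them → between/within variance
  of the amount part (and hence ρ) is unidentifiable; the fit falls back
  to a pooled amount part (σᵤ = 0, ρ = 0, flagged `amount_pooled`)
  instead of aborting a whole pipeline run over one sparse group.
* every person single-day in an amount-model group → identifiability
  error, by contract.

**Distribution of usual intake.**  Pseudo-persons resample observed
persons' covariate rows and draw random effects from the fitted
distribution.  Per day type (weekday/weekend), the conditional mean
amount is E[g⁻¹λ(m + ε)] by 9-point Gauss–Hermite over ε; for two-part
models it is multiplied by the consumption probability at u₁.  Usual
intake is the 5/7·weekday + 2/7·weekend combination, clipped at 0.  The
Box-Cox convention is g₁(y) = y − 1, and back-transform arguments outside
the domain (λz+1 ≤ 0) map to 0 — exact in the λ = 1 limit up to a
truncation term measured at ~0.01 g in the closed-form scenario.  The
default is 100 pseudo-persons per observed person; every distribution
takes an explicit seed and is bit-reproducible.

Percentiles are empirical; `pct_within` is computed as
100 − pct_below − pct_above so the three always sum to exactly 100.

**Reporting recovery on the measurement scale.**  The profile MLE of λ on
genuinely normal (λ = 1) data sits near 0.90–0.95 at realistic sample
sizes (scipy's independent Box-Cox MLE behaves identically), and
transformed-scale coefficients at λ̂ ≠ 1 are not commensurable with the
λ = 1 truth.  Recovery is therefore assessed via λ-invariant functionals
— the implied population mean, between-person SD and within-person SD of
daily intake on the gram scale (`implied_population_moments`) — which
equal (β₀, σᵤ, σₑ) exactly when λ = 1.  Measured over 20 seeds at 500
children × 3 days, their median absolute relative errors are ≈0.6%, 5%
and 1.5%.

## Pipeline

`analyze_cohort` chains: disaggregation/classification → age split → per
age group: energy amount-model fit (the usual-intake mean of energy feeds
target scaling; the raw day mean is reported alongside) → per-group model
fit and Monte Carlo distribution → summary, range-classification and
diet-gap tables, one row per food group in the conventional order.  The
red-meat aggregate is the day-level sum of beef+lamb and pork, modelled
as its own episodic group.  Per-group seeds derive deterministically from
the run seed.  Stage errors propagate annotated with the stage, group and
age-group label.

## Synthetic cohorts

The generator emulates a two-round pre-school food-record design: ~800
children aged 3–6.4 at round one, a 3-day round (two weekdays + one
weekend day) for everyone and, for the share implied by the record-day
mix (default 1/2/3/4/5 days at 1/5/69/1/24%), a later 2-day round offset
by 4–11 months — which also creates the children who cross the age-5
boundary.  Day-level group totals are drawn per group from configured
amount or two-part truths (defaults echo the consumption magnitudes
reported for Finnish pre-schoolers: dairy far above its cap, legumes and
nuts near zero, episodic meats/fish/eggs).  Totals are then inverted into
base-ingredient amounts — dairy split across categories so the
milk-equivalent-weighted sum matches the drawn total, added sugars split
across carriers by their sugar content and added fraction, cooked forms
divided by their form factors — partially wrapped into composite products
(curated dishes plus seeded random composites, including nested recipes
and a recipe containing an excluded ingredient), and topped up with
excluded fillers.  A per-day ledger of drawn totals and assembled energy
is the ground truth: the pipeline must reproduce it exactly (tested at
≤ 1e-6 relative, observed at ~1e-16).

The brute-force oracle integrates each simulated person's expected daily
intake over the residual by 161-point trapezoid quadrature on ±8 SD — a
deliberately different numerical route from the Gauss–Hermite
back-transform — so the agreement test (≤ 1 percentage point on
attainment; observed ≤ 0.15) genuinely cross-validates the machinery.

What the synthetic tests do **not** show: the generator's foods are a
small stylized library, not a real food-composition database; reporting
error, portion-size estimation bias and seasonal menus are absent; and
the truth models are exactly the fitted model family, so the tests
establish correctness of the estimation machinery, not robustness to
model misspecification.

## Problem sizes and defaults

Defaults: λ grid resolution 0.01; Gauss–Hermite 13 nodes/axis (joint
two-part), 9 nodes (back-transform), 21 (implied moments); L-BFGS-B ftol
1e-9; 100 pseudo-persons per observed person; weekend weights 5/7, 2/7.
The shipped checks use 20 recovery seeds at 500×3, 10⁶ persons for
oracle comparisons, 10⁵ draws for the closed-form limit, and 100–400
child cohorts for end-to-end runs — sizes at which every check is stable
across seeds while the whole suite stays desk-scale.

## Known limitations

* The λ search range is [0, 1]; heavier-than-linear transforms are out of
  scope (as in the method this follows).
* The two-part λ is estimated from the positive-day submodel, not jointly;
  at the shipped sample sizes the difference is within sampling noise.
* No survey weights and no confidence intervals for the population
  percentages; children contributing to both age groups are treated as
  independent within each fit.
* Added-sugar fractions, milk-equivalent assignments and recipes ship as
  editable configuration; the defaults are illustrative, not a specific
  study's tables.
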