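# Methods

`codredist` implements the redistribution stage of cause-of-death (CoD)
data processing for vital-registration (VR) data: deaths certified to
"garbage" codes — codes that cannot be the underlying cause of death
(UCoD) because they are impossible, too vague, a symptom, or an
intermediate/immediate cause — are reallocated to plausible underlying
causes so that the resulting cause-specific death counts are usable for
burden estimation and comparable across place and time.

## Cause hierarchy and garbage classification

Causes live in a levelled, mutually exclusive tree: level 0 is the
all-cause root; level 1 splits mortality into communicable/maternal/
neonatal/nutritional (CMNN), non-communicable (NCD), and injury causes;
levels 2–4 hold increasingly detailed causes (subtype leaves such as the
stroke subtypes sit at level 4 under their level-3 parent).  Raw ICD-style
codes are mapped to either a valid cause or a garbage *group* (a set of
diagnostically related garbage codes).  Code lookup normalises dialects —
uppercase, dots stripped — and coarsens unmapped 4-character codes to their
3-character stem, mirroring tabulation-list behaviour.

A garbage group's *class* grades its specificity by the span of its
plausible targets: class 1 spans two or more level-1 causes (sepsis-like
codes), class 2 a single level-1 cause (unspecified injuries), class 3 a
single level-2 cause (ill-defined cancer site), class 4 a single level-3
cause (unspecified stroke, whose targets are the stroke subtype leaves).
`infer_class` derives the class from a target set by counting distinct
ancestors at levels 1–3; stored classes are validated against it.  Classes
1–2 are "major garbage".

## Data-quality scoring

For each location-year the package computes

* **completeness** = VR deaths / estimated all-cause envelope, capped at 1
  (over-registration would otherwise push the score above 1);
* the **major-garbage fraction**, crude or age-standardised.  The
  age-standardised version takes a weighted mean of per-age-band fractions
  using a reference weight vector; bands with zero deaths are dropped and
  the weights renormalised rather than treated as 0% garbage, which would
  bias the standardised fraction downward;
* **PWC** (percent well certified) = completeness × (1 − major-garbage
  fraction);
* a **star grade**: the count of configured thresholds at or below the PWC
  (closed lower bound, so a PWC exactly at a cut earns the higher grade).
  The default thresholds are six equal-width bins on [0, 1]; real
  deployments should supply their own table, and the engine only assumes a
  strictly increasing sequence.

## Redistribution proportions

All four estimators emit the same object: per garbage group, a table of
(age, sex, location, year, target cause, proportion) with proportions
summing to 1 within every stratum.

### Multiple-cause analysis for intermediate causes

Intermediate causes (sepsis, heart failure, …) appear in the certificate's
Part I chain (and Part II contributing conditions) even when the UCoD is
valid, so well-coded certificates identify which underlying causes lead to
them.  Steps:

1. **Tag and aggregate.**  Certificates with a garbage UCoD are excluded.
   A certificate counts as intermediate-cause-related if any of the spec's
   codes appears in Part I — plus Part II when `include_part2` is set (the
   sepsis-style configuration is chain-only).  Records aggregate to
   per-(UCoD, age, sex, location, year) counts `n_i` and successes `Y_i·n_i`.
2. **Trim targets.**  Underlying causes are ranked by
   intermediate-cause-related deaths and the smallest prefix covering 80%
   kept (boundary ties all included, for order-independence).  The tail
   causes then get one more chance: the stratum fractions are regressed on
   tail-cause indicator columns under an L1 penalty, weighted by `n_i`
   (binomial precision), with columns standardised to unit weighted
   variance so rare causes are not over-penalised.  The penalty is chosen
   by 10-fold cross-validation with weighted squared error under the
   one-standard-error rule; tail causes with non-zero coefficients join the
   target set.  The 1-SE rule (rather than the bare CV minimum) is the
   deliberate default: in null simulations the CV-minimum penalty retains
   noise causes in roughly a third of runs, whereas 1-SE removes them
   essentially always while still catching large real effects; `rule="min"`
   is available.
3. **Fraction model.**  A binomial GLM with logit link:

       Y_i ~ Binomial(n_i, pi_i)
       logit(pi_i) = b0 + b1·X + b_age + b_sex + gamma_cause

   with categorical age/sex effects (first level is the reference) and a
   per-cause intercept.  The per-cause term is a *random* effect in spirit;
   it is implemented as sum-coded fixed effects shrunk toward zero by an
   exchangeable empirical-Bayes factor `tau^2/(tau^2 + s^2)` — flagged in
   the fit diagnostics as `exchangeable_shrinkage`.  Causes never observed
   in multiple-cause data predict with a zero cause effect (population-level
   prediction).  If the GLM fails outright (separation), a lightly
   ridge-penalised fit is used and flagged non-converged.  Zero-success
   strata are retained as ordinary binomial observations; no continuity
   correction.
4. **Proportions.**  Predicted fractions are multiplied by an external
   cause-specific death envelope, summed within stratum, and normalised.
   Strata with zero predicted intermediate-cause deaths are omitted.

A consistency caveat documented by the fit diagnostics and exercised in the
tests: when miscoding removes tagged certificates from the well-coded pool
at a constant rate, the fraction estimated from well-coded certificates is
`(1−r)·pi/(1−r·pi)`, not `pi`.  Composing it with the *observed* well-coded
cause deaths is then exactly proportional to the miscoded-death
distribution, whereas composing with true cause totals is slightly
inconsistent for high-fraction causes — the circular-dependency limitation
inherent to using externally estimated envelopes.

### Unspecified injuries

External-cause garbage (X59/Y34-style) is informed by the
*nature-of-injury* codes in the chain.  Chain codes collapse to a small set
of diagnostic groups (the shipped fixture uses 8; the configurable map
supports any number, e.g. the 37 groups used at production scale), and each
certificate contributes an unordered combination of groups.  From
certificates with a valid injury UCoD and those with the garbage UCoD the
package estimates

    P(combination_j | garbage UCoD)   and   P(injury cause_i | combination_j)

keeping the smallest most-frequent prefix of combinations covering 95%
(renormalised; retained combinations never observed with a valid cause are
dropped with a warning since their cause conditional is undefined).
Preliminary proportions are the composition
`sum_j P(combination_j|garbage) · P(cause_i|combination_j)`, computed
within a demographic cell when it has at least `min_cell` (default 50)
garbage certificates, else from the location pool, else globally — a
deterministic fallback ladder.  Applying them to the garbage certificates
gives attributed deaths per cause and stratum; the per-cause fraction
attributed/(attributed + correctly coded) is then modelled with the same
binomial fraction model and rescaled by an injuries-only envelope, so no
mass leaves the injury branch.  Part II codes do not enter combinations
(chain semantics); combinations are sets, not sequences.

### Negative correlation

Class-4 garbage (unspecified stroke/diabetes/cancer site) cannot appear on
a certificate alongside its own subtypes, so multiple-cause data are
uninformative.  Instead, per subtype, the logit of the subtype's share of
non-garbage subtype deaths is regressed linearly on mortality-predictive
covariates (shares clamped to [1e−4, 1−1e−4] before the logit).  Residuals
are regressed on logit(GC), the logit garbage fraction of the parent group;
a non-zero slope means coding practice leaks subtype deaths into the vague
code.  Each stratum's prediction is shifted by

    adjustment_i = b1 · (logit(GC0) − logit(GC_i))

with counterfactual GC0 = 1% (logit(0) being undefined), inverse-logit
transformed and renormalised over subtypes.  The shift is applied in logit
space by default (keeps shares in (0, 1) without clipping); a `natural`
switch adds it on the probability scale.  When all strata share one GC the
slope is undefined and the adjustment is zero, with a warning.  The
adjustment is exact when the draining bias is linear in logit(GC) over the
observed range — the synthetic draining scenario generates data under
precisely that assumption, so the benefit test demonstrates the estimator
works where its model holds, not that real-world draining is logit-linear.

### Impairments

Impairment garbage (anaemia-like) uses the non-fatal burden: the share of
years lived with disability (YLDs) each cause contributes to the
impairment, restricted to causes that carry years of life lost (a person
must be able to die of the target).  Locations with a star rating above 3
use their own YLD shares; others use region-pooled shares, where the pool
sums YLDs across the region's locations *before* dividing (so larger
locations weigh more) and is computed per stratum.

### Proportional redistribution

Within each stratum, garbage deaths are allocated proportionally to the
observed non-garbage deaths of the target set — every valid cause for
class-1 groups, the a-priori target list for class-3 groups.  The method
assumes garbage coding is independent of the underlying cause; the test
suite demonstrates both sides of that assumption (unbiased recovery under
independent miscoding, systematic error under cause-biased miscoding).
When a stratum's targets hold no deaths the proportions fall back
deterministically: stratum → same location-year pooled over ages and sexes
→ global pool → uniform over targets.

## Engine

`redistribute` removes garbage rows and credits each target with
`garbage × proportion` per stratum; totals are conserved exactly up to
float round-off, and a second pass is a no-op because no garbage remains.
Packages act on disjoint garbage groups and only ever target valid causes,
so application order is irrelevant.  Uncovered garbage strata raise in
strict mode or fall back to the stratum's observed non-garbage distribution
with a warning.  `run_pipeline` fits one package per configured group by
its declared method and reports the death mass moved per method; the tally
partitions total garbage exactly.  Deaths stay fractional throughout;
integerisation by largest remainder is available at export only.

## Synthetic worlds

The generator builds everything the methods consume, with stored ground
truth: a fixture hierarchy (3 level-1, 9 level-2, ~30 detailed causes with
ICD-style codes and a full garbage-group fixture), HAQ/SDI-like covariates
per location-year, populations with a reference age-weight vector, and
expected cause-specific deaths whose per-stratum cause mix varies by age
(injuries young, NCDs old), sex, and optionally a covariate tilt.  Defaults:
4 locations × 5 years × 20 age bands × 2 sexes, ~10^5 deaths.  All
randomness flows from one explicit seed through one `numpy` generator per
call.

Garbage mechanisms recode each death to its group's garbage code with a
constant probability (`cause_independent`) or per-cause rates
(`cause_biased`), recording the origin ledger.  Certificate simulation
draws intermediate-cause presence from the logistic model above with known
coefficients (per-cause effects centred to sum to zero, so the fitted
intercept is comparable to the generating one) and miscodes a known share
of tagged certificates to the garbage code; injury certificates carry
combinations drawn from stored per-cause conditionals.  The negative-
correlation scenario drains subtypes with differential intensity linear in
logit(GC), with GC driven by a coding-practice variable deliberately
absent from the covariate model.

What the generator does *not* emulate: realistic ICD code inventories,
within-certificate code sequences beyond the minimal chain structure,
reporting-delay or completeness dynamics, and spatial correlation between
neighbouring locations.  Passing tests therefore show the estimators are
correct under their stated assumptions at realistic stratification, not
that those assumptions hold in any particular registry.

## Numerical choices and problem sizes

Proportion packages validate to 1e−9 within-stratum sums; conservation is
asserted at 1e−9 relative.  Logit clamping uses eps = 1e−4.  The LASSO path
spans three decades below the smallest all-zero penalty on 60 grid points.
The test suite runs the certificate model at n = 10^5 certificates × 10
seeds for parameter recovery (all fixed effects within 3 standard errors in
≥9/10 seeds; mean pooled total-variation error of the recovered garbage-
origin distribution < 0.05), 50 replicates for the negative-correlation
benefit, 50 tiny worlds for conservation, and 20 null simulations for LASSO
specificity.  `scripts/acceptance.py` re-runs the full pipeline on one
seeded world and writes the measured quantities as JSON.

## Known limitations

* The binomial random intercept is approximated by shrunken fixed effects;
  a full integrated-likelihood GLMM would differ slightly for causes with
  very few strata.
* Age/sex splitting, misdiagnosis corrections (dementia, Parkinson's,
  atrial fibrillation), HIV misclassification, noise reduction, and
  uncertainty intervals on proportions are outside scope.
* Redistribution proportions inherit the envelope's biases (circularity);
  see the consistency caveat above.
* The star-threshold default is a placeholder scale, not a calibrated one.
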