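# Methods

## The substantiation model

The unit of analysis is the prescription: one outpatient visit's set of
ICD-10-CM diagnoses and ATC medications plus patient age and sex.  Repeat
visits by one patient are treated as independent prescriptions.

For every pair of codes co-occurring on at least one prescription the miner
records, per stratum (sex × 5-year age band, bands half-open `[5k, 5k+5)`)
and pooled over all strata, the joint and marginal prescription counts and
the lift

    Q(a, b) = P(a, b) / (P(a) P(b)) = n_joint · n_total / (n_a · n_b),

where probabilities are per-prescription frequencies.  Lift was chosen as
the association statistic because the default decision threshold α = 1 is
exactly lift's independence point; the formula is isolated behind one
function (`mining._q_value`) so an alternative ratio statistic can be
swapped in.  Design choices around the estimate:

* **No smoothing, no imputation.**  A pair with no record is *negative
  evidence*, not a Q = 0 estimate.  `min_support` (default 1) can drop
  low-count records but no support floor is imposed by default.
* **Pooled stratum always mined.**  Stratum-specific lookups fall back to
  the pooled estimate by default (`fallback="pooled"`), because sparse
  strata would otherwise make most lookups absent.
* **Pseudo-associations.**  Comorbidity can lend a medication a spurious
  lift with a disease that does not indicate it (insulin–hypertension via
  diabetes).  Two mitigations are provided: the classifier's default uses
  only the *maximum*-Q diagnosis per medication at decision time
  (equivalent to the existential test at a strict threshold), and
  `prune_global_top1` optionally discards all but the top-Q diagnosis per
  (stratum, medication) at the model level, breaking ties toward the
  lexicographically smaller diagnosis code.  Pruning is off by default.

### Classification

A medication is D–M positive if its best diagnosis on the prescription has
Q **strictly** greater than α (equality is negative), M–M positive likewise
against the other medications.  Under the default `dm_or_mm` rule a
medication is explained by either kind of evidence; the `dm_and_mm` variant
requires both, with the M–M clause vacuously true for single-medication
prescriptions (otherwise every monotherapy would be auto-flagged).  A
prescription is substantiated iff all its medications are explained.  The
unsubstantiated set is non-decreasing in α (a property test enforces
this), since raising the threshold can only withdraw evidence.

### Federated merging

Two mined tables combine one-shot into a hybrid: for each (stratum, pair)
present in both, the record with the larger joint co-occurrence count wins
(`n_joint` is the only co-occurrence frequency the models store); ties go
to the original model by default.  Pairs known to only one model are kept
under the default `union` policy or dropped under `intersection` — the
protocol's source is silent on unshared pairs, so both are offered.
Merged records are byte-identical to their source records; provenance
("O"/"L") is tracked per record in a side table and serialized with the
model.

## The synthetic generator

The generator is the package's test bed: it produces corpora whose
association structure is known in closed form, so the miner and classifier
can be validated against analytic expectations rather than against another
implementation.

Per prescription: draw sex (Bernoulli) and integer age (truncated normal),
then **k iid weighted draws** of diseases (k from a small fixed
distribution with mean ≈ 2.6, duplicates collapsed), apply comorbidity
rules, draw each present disease's indicated medications independently,
add companion medications (e.g. folate with methotrexate at 0.85),
optionally add diagnosis-independent *background* medications, force one
indicated medication if the set came up empty, and finally — with
probability `error_rate` — inject one medication indicated by *none* of
the prescription's diagnoses (an indicated medication of a uniformly
chosen absent disease), recording it in the label with a severity grade.

Key design decisions:

* **Fixed-size diagnosis draws, not independent prevalences.**  Real visit
  diagnosis lists are short and problem-focused: listing an unrelated
  condition *displaces* a medication's indication.  Drawing k diagnoses
  without replacement reproduces this — unindicated disease–medication
  pairs sit at lift ≈ 0.6–0.9, systematically below 1 — whereas
  independent per-disease coin flips would put every unindicated pair at
  lift exactly 1, where the strict Q > α test degenerates into a coin flip
  on estimation noise and no threshold could separate errors from noise.
* **Comorbidity as conditional add rules.**  `(A, B, p)`: if A is drawn and
  B absent, add B with probability p.  The shipped truth plants
  hypertension → type-2 diabetes at p = 0.35, giving insulin a
  pseudo-lift ≈ 2.4 with hypertension (strictly between 1 and its direct
  lift with diabetes).
* **Demographic presets.** `local` (age mean 53.4, SD 19.8, 36% male) and
  `original` (mean 46.6, SD 23.3, 45% male) share all structural truth but
  differ in population, so original/local/hybrid experiments compare
  models mined from genuinely different demographics.  Ages are truncated
  to [18, 95] (adult outpatient cohort).
* **Catalog scale.**  27 diseases (weights ≤ 0.06 before normalization,
  with age/sex modifiers), 34 indicated medications each with a unique
  indication, two companion rules.  Weights are sized so every planted
  indication pair has analytic lift ≥ 5 — strong, unambiguous indications.
* **Error severities** default to the observed outpatient mix: no
  life-threatening errors, 27/232 serious, 205/232 significant.
* **Reviewer simulation.**  Ground truth plays both raters with a label
  flip rate of 0.02 each (reproducing interrater κ ≈ 0.92–0.94 on balanced
  test sets) and a 0.0033 per-review chance of a sub-threshold confidence
  score on the 6-point scale.

### The analytic lift oracle

`analytic_lift` computes the expected lift of any planted pair in closed
form: disease presence probabilities come from inclusion–exclusion over
the k-draw process (`P(all of S drawn | k) = Σ_T⊆S (−1)^|T| (1−w_T)^k`,
marginalized over k and the stratum mix), corrected for comorbidity rules;
medication marginals combine the indication path, companion paths (with
pairwise overlap corrections) and a first-order injection term
`error_rate · P(indication absent) / E[#absent] · relw`.  Deliberately
ignored small terms — the forced non-empty-medication draw, second-order
injection interactions, companion-of-injected chains — each contribute
well under the 10% tolerance at the shipped parameters; in practice mined
pooled lifts at 200k prescriptions agree with the oracle to ≈ 3%.

## Evaluation protocol

Enriched test sets sample `n_per_class` prescriptions without replacement
from each *predicted* class (seeded, bit-reproducible).  Paired reviews are
excluded when **either** reviewer's confidence falls below 4 of 6;
disagreements are adjudicated by an optional third (senior) label, and an
unresolvable disagreement is an explicit error.  Metrics use
unsubstantiated as the positive class; undefined ratios (zero
denominators) are `None`/"NA", never 0, so degenerate sweeps cannot
silently inflate a table.  Metrics are carried at full precision and
rounded to two decimals only in the formatted report (α rows descending
1.5 → 0.5, models side by side).  Cohen's κ uses the agreement-based
large-sample SE, `SE = sqrt(p_o(1−p_o)/(n(1−p_e)²))`, for its 95% CI, and
is applied both to the binary substantiation labels and (restricted to
prescriptions both raters called unsubstantiated) to the 3-level severity
scale.  Group comparisons use the two-tailed t test for age (a zero
pooled-variance, equal-means degenerate case reports t = 0, p = 1),
chi-square for sex, and Wilcoxon rank-sum for diagnosis/medication counts.

## Problem sizes and numerical choices

The shipped experiments run at desk scale: 100k training and 5k test
prescriptions for parameter recovery, 50k per site for the hybrid
experiment, 200k for lift calibration.  At these sizes **stratified lift
estimates of weak pairs are unreliable** — a stratum holds a few thousand
prescriptions, so unindicated pairs (true stratum lift ≈ 0.8) are
estimated from joint counts of 5–70 and routinely fluctuate above 1,
wrongly explaining injected medications.  The scaled-down experiments
therefore mine pooled models (stratified mining remains the API default
and is exercised by the unit and property tests); stratification pays off
only at population scale, where per-stratum counts make that noise
negligible.  Relatedly, the generator's unindicated-pair lift floor
(≈ 0.65) means sweep thresholds below it lose all sensitivity at once —
real corpora, with heterogeneous association strengths, degrade more
smoothly.

Other numerical conventions: model files serialize floats with `repr` for
bit-exact round trips and carry a record count to detect truncation;
M–M pair keys are stored in canonical lexicographic order; all randomness
flows through a single seeded NumPy generator per stage, with per-stratum
draws consumed in sorted stratum order so runs are reproducible.

## What passing tests do and do not show

The generator's world is far simpler than real prescribing: medications
have unique indications, there are no dose/duration fields, no temporal
structure, no coding noise, and injected errors are uniformly random
rather than clinically patterned.  Recovery of injected errors at
sensitivity ≳ 0.9 therefore demonstrates that the estimator and decision
rule are implemented correctly and behave as the theory predicts — not
that comparable operating characteristics would be achieved on real EHR
extracts, where association strengths are weaker and pseudo-associations
richer.  Reproducing published operating characteristics on private
hospital test sets is explicitly out of scope.
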