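# Methods

## Scoring model

A screening instrument is a set of milestone items, each with a domain
(personal-social; language and logico-mathematical reasoning; fine
motor-adaptive; gross motor), an administration window in months, and two
norm ages: `p50_age`, where half the norm population passes, and
`p95_limit_age`, beyond which 95% pass. Scoring follows the Denver-style
convention:

- *pass* → Positive (+1);
- *fail* at or below the 95% limit age → Caution (0);
- *fail* strictly above it → Delay (−1);
- *couldn't observe / can't do it* (parent report only) → unanswered, no
  coefficient.

The boundary is deliberately strict-greater-than: a child exactly at the
limit age who fails still earns a Caution. An "age-appropriate" item is one
whose administration window contains the child's age; for parent booklets
the child receives the whole booklet of their age group (24–35 or 36–59
months), whatever the per-item windows say.

The overall raw score is the **mean** coefficient over answered applicable
items (domain scores restrict to one domain). The mean rather than the sum
keeps scores in [−1, 1] and comparable across children who face different
numbers of items; summed scores would conflate performance with age-driven
item counts. Direct assessments must answer every applicable item (the
assessor sees the full table); missing parent-report rows are coerced to
unanswered with a logged warning, since an unmarked booklet row and an
explicit "couldn't observe" are operationally the same thing.

## Classification

At risk ⇔ (Delays ≥ 1) ∨ (Cautions ≥ 2), plus (unanswered ≥ 4) for the
parent report; Not at risk is the logical complement. The unanswered
threshold is counted over the whole booklet, not per domain. The published
prose states the not-at-risk side with "or" between clauses, which read
literally contradicts the at-risk rule; we take the at-risk disjunction as
authoritative and define Not at risk as its negation.

## Diagnostic accuracy and agreement

Truth is the direct-assessment label, test the parent-report label,
positive = at risk. Proportion CIs use the Wilson score interval (well
behaved at n ≈ 50 and near the boundary, unlike Wald); likelihood-ratio CIs
use the Simel–Samsa–Matchar log method. With no false positives LR⁺ is
reported as +∞ with a flag rather than raising. Printed percentages round
half-up to the integer, LRs to two decimals.

Cohen's κ uses the Fleiss–Cohen–Everitt asymptotic SE with a normal 95% CI
truncated to [−1, 1], interpreted on the Landis–Koch bands (≤0.20 slight,
≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, ≤1.00 almost perfect;
negative = disagreement). Item-level association switches from Pearson χ²
(no Yates correction by default; flag available) to Fisher's exact test
when any **observed** cell is below five — the observed-cell convention,
rather than the textbook expected-cell rule, mirrors practice in the
screening literature this package serves; the `fisher_trigger` flag
restores the expected-cell convention. Effect size is signed φ on 2×2
tables and Cramér's V = √(χ²/(N·(min(r,c)−1))) generally; V = |φ| on 2×2.

Bayes updating is exact odds arithmetic: for any table with positive
margins, `posttest(prevalence, LR⁺) = PPV` and
`1 − posttest(prevalence, LR⁻) = NPV`; this identity is enforced by
property tests.

## ROC

Screening scores are mean coefficients where **lower = higher risk**; all
ROC entry points take a `low_is_risk` polarity flag (default true) and
orient scores internally. The empirical curve enumerates every distinct
threshold; its trapezoidal area equals the tie-adjusted concordance
probability (verified against O(n²) pair enumeration).

The binormal model puts negatives at N(0,1) and positives at N(μ, σ) on a
latent scale; with a = μ/σ and b = 1/σ, Az = Φ(a/√(1+b²)). Fitting follows
Dorfman–Alf: continuous scores are binned into at most 10 quantile
categories (`--roc-bins`), category thresholds are free parameters, and the
multinomial likelihood is maximized with L-BFGS-B from moment starts
(positive-class mean/SD standardized by the negative class; probit of
pooled cumulative frequencies for thresholds). b is bounded to (0.05, 20)
via log σ, threshold increments are log-parameterized to stay ordered, and
cell probabilities are floored at 1e−300 before logging. Fewer than two
distinct cutpoints raise a not-identifiable error — with a single binary
cutpoint a and b cannot both be estimated. Parameter recovery on
probit-simulated ratings (true a = 1.5, b = 1, n = 500/class, 50 seeds)
achieves mean absolute Az error ≈ 0.01.

The Youden scan reports J = Se + Sp − 1 per cutoff with ties broken toward
higher sensitivity (a screening instrument prefers catching cases).

## Individual change and group tests

NET = 100·(CARE − HLL)/HLL per child; undefined at HLL = 0, in which case
the record is flagged and excluded from aggregates (cell summaries are
means/medians of per-child NETs, not NETs of cell means). SID divides the
raw difference by the baseline (direct-assessment) SD. The RCI follows
Jacobson–Truax: difference over SD·√2·√(1−reliability), |RCI| ≥ 1.96
flagging reliable change; the reliability default (0.9) is a conventional
screening-instrument value and is configurable. Neither formula has a
single canonical source in the applied literature, so both conventions are
stated here explicitly.

Mann–Whitney U is computed from midrank sums with the tie-corrected normal
approximation; the effect size is r = |z|/√N, the convention that
reproduces the r magnitudes screening studies print alongside U (the
rank-biserial 1 − 2U/(n₁n₂) does not). One-way ANOVA reports
η² = SSb/SStot and ω² = (SSb − (k−1)·MSw)/(SStot + MSw) from sums of
squares, with pooled-variance Bonferroni post hoc t-tests and Cohen's d.
The mixed-design ANOVA uses the classic split-plot partition — group tested
against subjects-within-groups, source and source×group against the
subject-by-source error — validated against pingouin to machine precision;
with a two-level within factor sphericity is trivial. Two-sided p-values,
α = 0.05 throughout.

## Synthetic dyads

The generator produces the statistical structure the analysis assumes:

- **Norms.** Item 50%-pass ages spread evenly over [24, 52] months within
  each domain (11/20/9/7 items by default, 47 total, matched one-to-one
  across the two instruments); pass probability Φ((age − a50)/s + ability)
  with slope s = 1.5 months. The 95% limit age is derived as
  a50 + 1.645·s. Probit rather than logistic curves make the binormal ROC
  model exactly correct in one simulator limit, giving the ROC module a
  closed-form oracle. Direct administration windows run from ⌊a50⌋ (the
  invariant `admin_min ≤ p50` forbids opening later) to ⌈p95⌉ plus a
  configurable tail (default 2 months; sparse test banks use longer tails
  so every age keeps applicable items).
- **Ability.** Per-child, per-domain latent ability ~ N(0, 1); a delayed
  subpopulation of fraction π (default 0.6) is shifted by −δ. Ground truth
  is this latent binary flag, not a threshold on ability, so classifier
  performance has a well-defined target.
- **Channels.** The direct assessor observes the true skill with
  sensitivity/specificity 0.97/0.97. Parents report *not observed* with
  probability ν = 0.05, otherwise *yes* with probability 0.98 for attained
  skills and 0.15 for unattained ones, plus an additive SES-dependent bias
  (0, +0.04, −0.04) on the yes-probability. The high report-sensitivity
  default reflects the empirical pattern of parental over- rather than
  under-reporting at item level.
- **Calibration.** `calibrate_to_paper` bisects δ (falling back to π at
  maximal δ; both directions are monotone) until the direct-assessment
  at-risk prevalence hits 75% ± 3 points at n = 5000, using common random
  numbers so the objective is deterministic.

**Exact channel oracle.** The parent-report channel's sensitivity and
specificity against the direct classification are also computed by
exhaustive integration, independent of the simulation path: a dynamic
program propagates the joint distribution of truncated mark counts (Delay
flag, Cautions capped at 2, unanswered capped at 4 — exactly the
information the rules consume) through every item, per-domain ability is
integrated by 21-node Gauss–Hermite quadrature, and the result is mixed
over delayed status, SES level and integer ages. On sparse banks the
Monte-Carlo pipeline agrees with this oracle to well under ±0.03.

**What the generator does not emulate.** Item difficulties are evenly
spaced, abilities are Gaussian and domain-independent given delay status,
and the reporting channel is item-independent. Two structural features
deserve emphasis when reading synthetic results. First, because
administration windows must open at the 50%-pass age, roughly half of
typical children fail a freshly applicable item, so over-referral of
typical children is intrinsic — consistent with validation cohorts in this
design, where most screened children are flagged. Second, the age-group
booklet asks parents about items ahead of young children within the group,
and every "no" is scored against age norms, so the synthetic parent report
over-flags (specificity ≈ 0.3 at the calibrated operating point) even
though its sensitivity is high. Passing tests therefore demonstrate
internal consistency of the pipeline and correctness of each statistic
against oracles — not that a real parent booklet would achieve any
particular specificity.

## Problem sizes

Calibration and channel recovery use n = 5000 simulated children; the
worked example and fixture cohorts use the study-sized n = 52; binormal
recovery uses 50 replicates at 500 per class; exhaustive oracles cover all
count triples ≤ 10 (classification) and all 2×2 tables with N ≤ 30
(Fisher). These sizes put Monte-Carlo error well inside the asserted
tolerances while keeping the full suite around a minute of compute.

## Known limitations

- Weighted and multi-rater κ, ROC confidence bands, and covariate-adjusted
  ROC regression are out of scope.
- The binormal fit needs ≥3 occupied rating categories; heavily tied scores
  at small n can be unfittable (the driver logs and skips, reporting the
  empirical curve only).
- The NET index is undefined for children whose direct-assessment score is
  exactly zero; such records are flagged, not imputed.
- Group tests in the driver are skipped (with a logged warning) when a
  demographic split leaves a degenerate cell; they do not abort the run.
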