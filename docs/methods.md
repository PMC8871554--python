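# Methods

## Checklist model

A checklist is a flat ordered list of components, each with an item number,
an optional subitem letter, an ordered element list, a study-type
applicability mark (`development_only`, `validation_only`, `both`), an
NA-eligibility flag and a score-exclusion flag. The shipped TRIPOD instance
encodes 22 items / 37 components / 25 subitems; components
{10c, 10e, 12, 13c, 17, 19a} are validation-only, {10a, 10b, 14a, 14b, 15a,
15b} development-only, {5c, 10a, 11, 14b, 17} NA-eligible, and item 21 is
excluded from scoring. Element lists follow the checklist's published
wording, one element per requirement clause; the title component carries
its four documented elements (study-type term, model term, target
population, predicted outcome) and the abstract component its ten summary
elements. The `referenced` response option is enabled for all elements
outside the title/abstract/introduction items, which by their nature cannot
point to another publication.

A note on denominators: the applicability marks imply 36 applicable
components for combined development-and-validation studies, 30 for
validation-only and 30 for development-only studies (37 minus item 21 minus
the six components of the other type). Some descriptions of this scoring
scheme state a maximum of 29 for development-only studies; that figure is
inconsistent with the marks themselves, so this package follows the
explicit applicability lists and reports 30.

## Scoring rules

- A component is adhered iff every element response is `yes` or
  `referenced` after dropping element-level NA responses.
- NA granularity is configurable (`na_mode`). Default `all_elements`: an
  NA-eligible component leaves the denominator only when *all* its elements
  are rated NA; partial NAs are simply dropped from the all-of check.
  `any_element` instead treats any NA element as marking the component not
  applicable. The underlying rating forms are ambiguous between the two
  readings; the default reconciles element-level NA options with
  component-level NA eligibility.
- An all-NA rating on a component that is not NA-eligible is a validation
  error, mirroring forms that simply do not offer the option.
- Item 21 responses are retained and reported descriptively in the
  per-component table (flagged non-scoreable) but never enter a score.
- Scores are exact `Fraction`s; percentages are rendered to one decimal
  only at output boundaries, so threshold counts (≥ 50 %, ≥ 75 %) are exact.

## Consensus

Consensus requires an explicit adjudication entry for every disagreeing
(study, component, element) triple — there is no silent default — with an
optional strict-majority mode that errors on exact ties. Any pair of
distinct responses counts as a disagreement, including adherence-equivalent
pairs such as `yes` vs `referenced`, because the resolution rule belongs to
the adjudicator, not the detector.

## Exact Mann–Whitney U test

U is computed from midranks of the pooled sample. Without ties the exact
null distribution comes from the Gaussian-binomial counting recurrence in
integer arithmetic (probabilities sum to exactly 1); with ties the complete
permutation distribution is enumerated while `C(n1+n2, n1)` ≤ 5×10⁵
(enumeration in Python is the binding cost, and every exactness guarantee
in the tests lies far below this bound), beyond which a tie-corrected
normal approximation with continuity correction is used; the `method` field
records which path produced the p-value. The two-sided p-value sums null
probabilities of outcomes with |U − n₁n₂/2| at least the observed value
(point-probability rule); tail-doubling is available via a flag. The two
rules coincide without ties because the null distribution of U is
symmetric. Adherence scores are discrete rationals, so the tied paths are
the common case, not an edge case.

## Beta regression

The mean submodel uses a logit link, the precision submodel a log link.
Fitting is by maximum likelihood through statsmodels' beta-regression
model, polished with a tight-gradient BFGS step so that fitted values are
invariant (≤ 1e-8) under reparameterisations such as shifting the year
centering; the convergence flag is derived from the actual score norm at
the reported optimum. The covariance is the inverse observed information.
Tests: Wald z per coefficient; a likelihood-ratio test against the refitted
null model for dummy blocks (df = number of dummies). Model-adjusted
category means are inverse-logit linear predictors at each level's dummy
pattern with all other mean-submodel covariates at their sample means.

Design construction: year enters both submodels centered (default: sample
mean year; the choice affects only intercepts); journal category is
dummy-coded against a configurable reference (default Dermatology, the
level with the largest adjusted mean in the motivating corpus); impact
factor enters linearly, with non-indexed journals recorded as 0. Scores of
exactly 0 or 1 lie outside the beta support; optional boundary compression
`(y·(n−1)+0.5)/n` is applied to the whole sample and flagged on the design.

## Synthetic corpus generator

Per study: covariates are drawn (study type and journal category by
largest-remainder allocation of the configured frequencies, so the default
42-study corpus reproduces its reference composition exactly; years with
linearly increasing weights to mimic rising publication activity; impact
factor uniform on 0–26, median ≈ 12.5), then a latent adherence probability
θ ~ Beta(μφ, (1−μ)φ) with logit(μ) and log(φ) linear in the covariates.
Each applicable component is adhered independently with probability θ
(conditional independence given θ is the simplest structure consistent with
a score-level beta model); NA-eligible components are rated NA with
probability `na_rate` (default 0.25 — in audit corpora a couple of the five
eligible components tend to be NA in most studies and the rest rarely, and
a flat rate is the simplest emulation). Adhered components render as
all-positive elements with `referenced` substituted at rate 0.1 where
allowed; a non-adhered component carries exactly one `no` (the minimal
perturbation, keeping element-level structure testable without inventing
element-difficulty parameters). Reviewer copies perturb each element with
probability `disagreement_rate` (default 0.02, six reviewers).

Default effect sizes: mean intercept 0.506 on the logit scale for a
reference-category study at the centering year (2005) with category offsets
ordered Dermatology > Medicine > Oncology > Public Health >
Multidisciplinary > Other, giving a corpus-wide mean score near 0.57 and
realized scores roughly between 0.3 and 0.8; a mild positive year trend
(+0.02/yr) in the mean and a negative year trend (−0.03/yr) in the
precision, so score variability grows in recent years; a −1.0 logit offset
for the two non-original publications, which therefore sit at the bottom of
the score range and motivate the original-articles-only filter before trend
fitting. The category counts of the reference composition are used as
relative frequencies (they are published as 15/12/4/4/2/3, which sums to 40
rather than the 42 studies; the allocation at n = 42 follows the largest
remainders).

What the generator does *not* emulate: element-difficulty heterogeneity,
correlated adherence between related components, reviewer-specific bias or
drift, and real journals' year–category correlations. Passing tests
therefore validate the pipeline's algebra and the estimators' calibration
under the stated model, not the substantive behaviour of any real corpus.

## Recovery benchmark and calibration

`recovery_benchmark_config` defines the reference recovery experiment: 200
studies, year-only model (β_year = 0.03, constant precision e³), one
unperturbed reviewer so replicates isolate score sampling noise. Across
replicates the mean-submodel coefficients are recovered nearly unbiasedly
with 95 % Wald coverage close to nominal. The fitted precision intercept is
systematically below the latent e³: realized scores are adherent-component
counts over denominators of ~30, so element-level binomial noise adds to
the latent beta variance and the fitted φ absorbs it. This is a property of
scoring, not an estimator defect; mean-structure inference is unaffected.

Problem sizes used by the shipped experiments: 1000+ randomized rating sets
for the scorer/oracle equivalence; all n₁, n₂ ≤ 8 for rank-test
enumeration equality and n₁, n₂ ≤ 12 for null-distribution properness;
5000 null replicates at the 7-vs-35 group split for type-I calibration;
500 replicates at n = 200 for Wald coverage and one n = 1000 corpus for
point recovery.

## Known limitations

- The exact rank test's tied-case enumeration bound trades exactness for
  time above C(n1+n2, n1) > 5×10⁵; the recorded `method` makes the switch
  auditable.
- Beta-regression inference is asymptotic; at corpus sizes around 40 the
  likelihood-ratio category test can be mildly liberal.
- Journal-category assignment (first-listed JCR category; non-indexed and
  proceedings → "Other") is documented data-preparation guidance, not
  computed by the package.
- No component weighting is offered: equal weights keep scores comparable
  across audits, at the cost of treating very different requirements as
  exchangeable.
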