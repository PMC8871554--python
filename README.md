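# tripod-adherence

Toolkit for quantifying how completely clinical prediction-model studies
report their methods and results against an itemised reporting checklist.
The shipped checklist instance is TRIPOD (Transparent Reporting of a
multivariable prediction model for Individual Prognosis Or Diagnosis):
22 items that expand into 37 rateable *components* (items or lettered
subitems such as `10c`), each holding one or more *elements* — the
individually rated requirement clauses.

The package is aimed at meta-researchers running reporting-quality audits:
it covers the full workflow from multi-reviewer element-level ratings
through consensus adjudication, adherence scoring, corpus descriptives and
exact rank tests, to beta-regression trend models — plus a synthetic corpus
generator so the whole pipeline can be exercised and calibrated without any
confidential rating data.

## The score and the models

A component is **adhered** when every applicable element is answered `yes`
or `referenced` (information available via a cited publication); a single
`no` breaks it. The study-level adherence score is

```
score = (# adhered components) / (# applicable components)
```

where applicability depends on the study type — components marked D apply
only when a model is developed, V only when one is validated — and item 21
(availability of supplementary material) never enters the score. Five
components (5c, 10a, 11, 14b, 17) may be rated *not applicable*, which
removes them from the denominator. For TRIPOD the denominator is at most 36
(development + validation), 30 (validation-only) and 30 (development-only).
Scores are kept as exact rationals so threshold proportions (≥ 50 %, ≥ 75 %)
never hinge on float rounding.

Group contrasts use the **exact Mann–Whitney U test**: without ties the null
distribution of U comes from the classical counting recurrence (exact
integer arithmetic); with ties the complete permutation distribution is
enumerated when feasible, otherwise a tie-corrected normal approximation is
used and the method is recorded in the result.

Temporal and journal effects are modelled with **variable-dispersion beta
regression**: score `y ∈ (0,1)` follows `Beta(μφ, (1−μ)φ)` with
`logit(μ) = xᵀβ` and `log(φ) = zᵀγ`, so publication year can shift both the
mean score and its variability. Model-adjusted category means evaluate the
fitted mean at each journal-category dummy pattern with all other
covariates at their sample means.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_corpus_summary_and_comparison.py` scores the default
42-study synthetic corpus and prints:

```
n = 42 studies
median adherence  : 60.0%
range             : 31.0% - 83.3%
share >= 50%      : 86%
share >= 75%      : 17%

development+validation (n=7) median 63.9% vs development (n=35) median 58.6%
two-sided p = 0.026 (normal_approx_ties); ...
```

The median/range describe the corpus score distribution; the final line is
the exact-rank-test comparison of combined development-and-validation
studies against development-only studies, with the tie-handling method
recorded. The same pipeline is available as a single shell command:

```sh
adherence pipeline --seed 1 --out out/
```

which writes the corpus CSVs, per-study scores, the per-component adherence
table and a JSON report. Individual steps are exposed as
`adherence simulate | disagreements | consensus | score | item-table |
summarize | compare | trend | validate-checklist`.

## Layout

- `src/tripod_adherence/checklist.py` — checklist model, validation, applicability
- `src/tripod_adherence/ratings.py` — rating/metadata I/O, disagreements, consensus
- `src/tripod_adherence/scoring.py` — component/study/corpus adherence scoring
- `src/tripod_adherence/stats.py` — descriptives, ECDF, exact Mann–Whitney
- `src/tripod_adherence/betareg.py` — variable-dispersion beta regression
- `src/tripod_adherence/simulate.py` — synthetic corpus generator, recovery harness
- `src/tripod_adherence/data/tripod.json` — the shipped checklist definition
- `docs/methods.md` — modelling assumptions, defaults and limitations
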