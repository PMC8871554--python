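"""Corpus descriptives and an exact rank test between study-type groups.

Scores the default 42-study synthetic corpus, prints the median / range /
threshold proportions of the adherence-score distribution, and compares
development-only studies against combined development-and-validation
studies with the exact Mann-Whitney U test.
"""

from tripod_adherence import (
    GeneratorConfig,
    StudyType,
    apply_consensus,
    compare_groups,
    generate_corpus,
    load_tripod,
    score_corpus,
    summarize,
    truth_adjudications,
)

defn = load_tripod()
studies, ratings, truth = generate_corpus(GeneratorConfig(seed=1), defn)
consensus = apply_consensus(ratings, truth_adjudications(truth, ratings, defn))
corpus = score_corpus(consensus, studies, defn)

s = summarize([res.score for res, _ in corpus])
print(f"n = {s.n} studies")
print(f"median adherence  : {100 * float(s.median):.1f}%")
print(f"range             : {100 * float(s.min):.1f}% - {100 * float(s.max):.1f}%")
print(f"share >= 50%      : {float(s.proportion_ge_50):.0%}")
print(f"share >= 75%      : {float(s.proportion_ge_75):.0%}")

cmp = compare_groups(
    corpus, lambda st: st.study_type is StudyType.DEVELOPMENT_AND_VALIDATION
)
print()
print(
    f"development+validation (n={cmp.summary_in.n}) median "
    f"{100 * float(cmp.summary_in.median):.1f}% vs development "
    f"(n={cmp.summary_out.n}) median {100 * float(cmp.summary_out.median):.1f}%"
)
print(
    f"two-sided p = {cmp.test.p_two_sided:.3f} ({cmp.test.method}); "
    "scores are discrete rationals, so ties are expected and the method "
    "field records how the null distribution was obtained."
)
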