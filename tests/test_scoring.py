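from fractions import Fraction

import numpy as np
import pytest

from tripod_adherence import (
    AdherenceStatus,
    RatingSet,
    Response,
    ScoringError,
    StudyRecord,
    StudyType,
    component_adherence,
    corpus_filter,
    generate_corpus,
    item_adherence_table,
    score_corpus,
    scoreable_components,
    study_score,
    truth_adjudications,
    apply_consensus,
    GeneratorConfig,
)
from oracles import oracle_study_score, random_consensus


def study(study_id="S1", study_type=StudyType.DEVELOPMENT_AND_VALIDATION):
    return StudyRecord(study_id, study_type, 2015, "Oncology", 5.0)


def full_consensus(defn, study_type, default=Response.YES, overrides=None):
    """Complete consensus rating with every applicable element at `default`."""
    overrides = overrides or {}
    responses = {}
    for comp in scoreable_components(defn, study_type) + [defn.component("21")]:
        if not comp.applicability.applies_to(study_type):
            continue
        for e in comp.elements:
            key = (comp.component_id, e.element_id)
            responses[key] = overrides.get(key, default)
    return RatingSet("S1", "consensus", responses)


class TestComponentAdherence:
    def test_all_yes_adheres(self, tripod):
        comp = tripod.component("7a")
        resp = {e.element_id: Response.YES for e in comp.elements}
        ca = component_adherence(resp, comp, StudyType.DEVELOPMENT)
        assert ca.status is AdherenceStatus.ADHERED

    def test_all_referenced_adheres(self, tripod):
        comp = tripod.component("7a")
        resp = {e.element_id: Response.REFERENCED for e in comp.elements}
        ca = component_adherence(resp, comp, StudyType.DEVELOPMENT)
        assert ca.status is AdherenceStatus.ADHERED

    def test_single_no_breaks_adherence(self, tripod):
        comp = tripod.component("10b")
        resp = {e.element_id: Response.YES for e in comp.elements}
        resp[comp.elements[1].element_id] = Response.NO
        ca = component_adherence(resp, comp, StudyType.DEVELOPMENT)
        assert ca.status is AdherenceStatus.NOT_ADHERED

    def test_na_rating_of_eligible_component(self, tripod):
        comp = tripod.component("17")
        resp = {e.element_id: Response.NOT_APPLICABLE for e in comp.elements}
        ca = component_adherence(resp, comp, StudyType.VALIDATION)
        assert ca.status is AdherenceStatus.NOT_APPLICABLE
        assert not ca.scoreable

    def test_inapplicable_component_is_na(self, tripod):
        comp = tripod.component("10c")  # validation-only
        ca = component_adherence({}, comp, StudyType.DEVELOPMENT)
        assert ca.status is AdherenceStatus.NOT_APPLICABLE

    def test_missing_element_is_an_error(self, tripod):
        comp = tripod.component("10b")
        resp = {comp.elements[0].element_id: Response.YES}
        with pytest.raises(ScoringError, match=comp.elements[1].element_id):
            component_adherence(resp, comp, StudyType.DEVELOPMENT)

    def test_all_na_on_non_eligible_component_rejected(self, tripod):
        # NA-allowing elements on a component that is itself not NA-eligible
        from dataclasses import replace

        comp = replace(tripod.component("5c"), na_eligible=False)
        resp = {e.element_id: Response.NOT_APPLICABLE for e in comp.elements}
        with pytest.raises(ScoringError, match="NA-eligible"):
            component_adherence(resp, comp, StudyType.DEVELOPMENT)

    def test_na_element_on_disallowing_element_rejected(self, tripod):
        comp = tripod.component("9")
        resp = {e.element_id: Response.NOT_APPLICABLE for e in comp.elements}
        with pytest.raises(ScoringError, match="does not allow"):
            component_adherence(resp, comp, StudyType.DEVELOPMENT)

    def test_na_mode_switch(self, tripod):
        # a two-element NA-eligible component built from 5c's schema
        from dataclasses import replace

        base = tripod.component("5c")
        elem = base.elements[0]
        comp = replace(
            base,
            elements=(elem, replace(elem, element_id="e2")),
        )
        resp = {"e1": Response.NOT_APPLICABLE, "e2": Response.YES}
        strict = component_adherence(resp, comp, StudyType.DEVELOPMENT)
        assert strict.status is AdherenceStatus.ADHERED  # NA element dropped
        loose = component_adherence(
            resp, comp, StudyType.DEVELOPMENT, na_mode="any_element"
        )
        assert loose.status is AdherenceStatus.NOT_APPLICABLE


class TestStudyScore:
    def test_perfect_dev_and_val_study(self, tripod):
        cons = full_consensus(tripod, StudyType.DEVELOPMENT_AND_VALIDATION)
        res = study_score(cons, study(), tripod)
        assert (res.numerator, res.denominator) == (36, 36)
        assert res.score == 1

    def test_na_components_leave_denominator(self, tripod):
        # all five NA-eligible components rated NA; 3 of the remaining 31 fail
        overrides = {}
        for cid in ("5c", "10a", "11", "14b", "17"):
            for e in tripod.component(cid).elements:
                overrides[(cid, e.element_id)] = Response.NOT_APPLICABLE
        for cid in ("1", "2", "9"):
            e0 = tripod.component(cid).elements[0]
            overrides[(cid, e0.element_id)] = Response.NO
        cons = full_consensus(
            tripod, StudyType.DEVELOPMENT_AND_VALIDATION, overrides=overrides
        )
        res = study_score(cons, study(), tripod)
        assert (res.numerator, res.denominator) == (28, 31)
        assert res.score == Fraction(28, 31)

    def test_half_adherent_validation_study(self, tripod):
        comps = scoreable_components(tripod, StudyType.VALIDATION)
        overrides = {}
        for comp in comps[:15]:
            e0 = comp.elements[0]
            overrides[(comp.component_id, e0.element_id)] = Response.NO
        cons = full_consensus(tripod, StudyType.VALIDATION, overrides=overrides)
        res = study_score(
            cons, study(study_type=StudyType.VALIDATION), tripod
        )
        assert (res.numerator, res.denominator) == (15, 30)
        assert res.score == Fraction(1, 2)

    def test_item_21_rated_but_never_scored(self, tripod):
        overrides = {("21", "e1"): Response.NO}
        cons = full_consensus(
            tripod, StudyType.DEVELOPMENT_AND_VALIDATION, overrides=overrides
        )
        res = study_score(cons, study(), tripod)
        ca = res.component("21")
        assert ca.status is AdherenceStatus.NOT_ADHERED
        assert not ca.scoreable
        assert (res.numerator, res.denominator) == (36, 36)

    @pytest.mark.parametrize("study_type", list(StudyType))
    def test_matches_exhaustive_oracle(self, tripod, study_type):
        rng = np.random.default_rng(hash(study_type.value) % 2**31)
        for i in range(200):
            cons = random_consensus(rng, tripod, study_type, f"S{i}")
            res = study_score(
                cons,
                study(f"S{i}", study_type=study_type),
                tripod,
            )
            assert (res.numerator, res.denominator) == oracle_study_score(
                cons, study_type, tripod
            )

    def test_flipping_no_to_yes_never_decreases_score(self, tripod):
        rng = np.random.default_rng(11)
        for i in range(30):
            cons = random_consensus(rng, tripod, StudyType.DEVELOPMENT, "S")
            base = study_score(cons, study(study_type=StudyType.DEVELOPMENT), tripod)
            nos = [k for k, v in cons.responses.items() if v is Response.NO]
            if not nos:
                continue
            key = nos[int(rng.integers(len(nos)))]
            flipped = RatingSet(
                "S", "consensus", {**cons.responses, key: Response.YES}
            )
            res = study_score(
                flipped, study(study_type=StudyType.DEVELOPMENT), tripod
            )
            assert res.score >= base.score

    def test_denominator_law(self, tripod):
        rng = np.random.default_rng(5)
        for st in StudyType:
            for i in range(50):
                cons = random_consensus(rng, tripod, st, "S")
                res = study_score(cons, study(study_type=st), tripod)
                n_na_rated = sum(
                    1
                    for comp in scoreable_components(tripod, st)
                    if comp.na_eligible
                    and all(
                        cons.responses[(comp.component_id, e.element_id)]
                        is Response.NOT_APPLICABLE
                        for e in comp.elements
                    )
                )
                assert res.denominator == len(scoreable_components(tripod, st)) - n_na_rated

    def test_response_order_invariance(self, tripod):
        rng = np.random.default_rng(9)
        cons = random_consensus(rng, tripod, StudyType.DEVELOPMENT, "S")
        keys = list(cons.responses)
        shuffled = RatingSet(
            "S",
            "consensus",
            {k: cons.responses[k] for k in reversed(keys)},
        )
        a = study_score(cons, study(study_type=StudyType.DEVELOPMENT), tripod)
        b = study_score(shuffled, study(study_type=StudyType.DEVELOPMENT), tripod)
        assert (a.numerator, a.denominator) == (b.numerator, b.denominator)


class TestItemTableAndFilters:
    @pytest.fixture(scope="class")
    @staticmethod
    def scored_corpus(tripod):
        cfg = GeneratorConfig(seed=21)
        studies, ratings, truth = generate_corpus(cfg, tripod)
        cons = apply_consensus(ratings, truth_adjudications(truth, ratings, tripod))
        return score_corpus(cons, studies, tripod)

    def test_counts_match_recount_oracle(self, tripod, scored_corpus):
        rows = {r.component_id: r for r in item_adherence_table(scored_corpus, tripod)}
        for comp in tripod.components:
            n_app = n_adh = 0
            for res, _ in scored_corpus:
                ca = res.component(comp.component_id)
                if ca.status is AdherenceStatus.NOT_APPLICABLE:
                    continue
                n_app += 1
                n_adh += ca.status is AdherenceStatus.ADHERED
            row = rows[comp.component_id]
            assert (row.n_adhered, row.n_applicable_studies) == (n_adh, n_app)

    def test_small_corpus_proportion(self, tripod):
        overrides = {("8", "e1"): Response.NO}
        sets, studies = [], []
        for i, ok in enumerate([True, True, False]):
            cons = full_consensus(
                tripod,
                StudyType.DEVELOPMENT,
                overrides={} if ok else dict(overrides),
            )
            sets.append(RatingSet(f"S{i}", "consensus", cons.responses))
            studies.append(study(f"S{i}", StudyType.DEVELOPMENT))
        corpus = score_corpus(sets, studies, tripod)
        row = next(
            r for r in item_adherence_table(corpus, tripod) if r.component_id == "8"
        )
        assert (row.n_adhered, row.n_applicable_studies) == (2, 3)
        assert row.proportion == Fraction(2, 3)

    def test_never_applicable_component_has_undefined_proportion(self, tripod):
        cons = full_consensus(tripod, StudyType.DEVELOPMENT)
        corpus = score_corpus(
            [cons], [study(study_type=StudyType.DEVELOPMENT)], tripod
        )
        row = next(
            r for r in item_adherence_table(corpus, tripod) if r.component_id == "10e"
        )
        assert row.n_applicable_studies == 0
        assert row.proportion is None

    def test_subgroup_restriction(self, tripod, scored_corpus):
        rows = item_adherence_table(
            scored_corpus, tripod, subgroup=StudyType.DEVELOPMENT_AND_VALIDATION
        )
        n_dv = sum(
            1
            for _, s in scored_corpus
            if s.study_type is StudyType.DEVELOPMENT_AND_VALIDATION
        )
        assert all(r.n_applicable_studies <= n_dv for r in rows)

    def test_corpus_filter(self, scored_corpus):
        out = corpus_filter(scored_corpus, lambda s: s.is_original_article)
        assert len(out) == len(scored_corpus) - 2
        assert corpus_filter(scored_corpus, lambda s: True) == scored_corpus
        flagged = corpus_filter(scored_corpus, lambda s: s.cites_tripod)
        assert len(flagged) == 3
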