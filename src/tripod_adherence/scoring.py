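"""Adherence scoring: per-component status, study scores, corpus item tables.

A component is *adhered* when every applicable element is answered ``yes``
or ``referenced``; a single ``no`` breaks it.  The study-level overall score
is the number of adhered components divided by the number of applicable
components, with the availability-of-supplementary-material item (item 21
in TRIPOD) excluded from both counts.  Components inapplicable to the study
type, and NA-eligible components actually rated not-applicable, leave the
denominator.  Scores are kept as exact rationals (numerator / denominator)
so that threshold proportions (>= 50 %, >= 75 %) never depend on float
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import pandas as pd

from .checklist import ChecklistDefinition, Component, StudyType
from .ratings import RatingSet, Response, StudyRecord

__all__ = [
    "AdherenceStatus",
    "ComponentAdherence",
    "AdherenceResult",
    "ItemAdherenceRow",
    "ScoringError",
    "component_adherence",
    "study_score",
    "score_corpus",
    "item_adherence_table",
    "item_table_frame",
    "corpus_filter",
    "corpus_scores_frame",
]

Corpus = list[tuple["AdherenceResult", StudyRecord]]


class ScoringError(ValueError):
    """Ratings are incomplete or inconsistent with the checklist."""


class AdherenceStatus(str, Enum):
    ADHERED = "adhered"
    NOT_ADHERED = "not_adhered"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ComponentAdherence:
    """Rated status of one component for one study.

    ``scoreable`` is False for components outside the score denominator:
    those excluded by design (item 21), inapplicable to the study type, or
    rated not-applicable.  Item 21 keeps its descriptive adhered /
    not-adhered status while staying out of the score.
    """

    component_id: str
    status: AdherenceStatus
    scoreable: bool = True


@dataclass(frozen=True)
class AdherenceResult:
    """Per-component statuses plus the overall adherence score for a study."""

    study_id: str
    per_component: tuple[ComponentAdherence, ...]
    numerator: int
    denominator: int

    @property
    def score(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def score_float(self) -> float:
        return self.numerator / self.denominator

    @property
    def score_pct(self) -> float:
        return 100.0 * self.numerator / self.denominator

    def component(self, component_id: str) -> ComponentAdherence:
        for ca in self.per_component:
            if ca.component_id == component_id:
                return ca
        raise KeyError(component_id)


@dataclass(frozen=True)
class ItemAdherenceRow:
    """Corpus-level adherence of one component.

    ``proportion`` is None when the component was applicable in no study
    (e.g. components rated not-applicable everywhere), mirroring how such
    rows are reported as undetermined rather than zero.
    """

    component_id: str
    n_adhered: int
    n_applicable_studies: int
    scoreable: bool = True

    @property
    def proportion(self) -> Fraction | None:
        if self.n_applicable_studies == 0:
            return None
        return Fraction(self.n_adhered, self.n_applicable_studies)


def component_adherence(
    responses: Mapping[str, Response],
    component: Component,
    study_type: StudyType,
    *,
    na_mode: str = "all_elements",
) -> ComponentAdherence:
    """Rate one component from its element responses.

    Not-applicable when the component is excluded from scoring, does not
    apply to the study type, or (if NA-eligible) was rated NA.  Otherwise
    adhered iff every non-NA element response is ``yes`` or ``referenced``.

    ``na_mode`` controls when NA element ratings remove an NA-eligible
    component from the denominator: ``"all_elements"`` (default) requires
    every element to be NA; ``"any_element"`` treats a single NA element as
    marking the whole component not applicable.
    """
    if na_mode not in ("all_elements", "any_element"):
        raise ValueError(f"unknown na_mode {na_mode!r}")
    if component.excluded_from_score or not component.applicability.applies_to(
        study_type
    ):
        return ComponentAdherence(
            component.component_id, AdherenceStatus.NOT_APPLICABLE, scoreable=False
        )

    values: list[Response] = []
    n_na = 0
    for elem in component.elements:
        if elem.element_id not in responses:
            raise ScoringError(
                f"component {component.component_id!r}: missing response for "
                f"element {elem.element_id!r}"
            )
        r = responses[elem.element_id]
        if r is Response.NOT_APPLICABLE:
            if not elem.na_allowed:
                raise ScoringError(
                    f"component {component.component_id!r}: element "
                    f"{elem.element_id!r} rated not_applicable but does not "
                    "allow it"
                )
            n_na += 1
        else:
            if r is Response.REFERENCED and not elem.referenced_allowed:
                raise ScoringError(
                    f"component {component.component_id!r}: element "
                    f"{elem.element_id!r} rated referenced but does not allow it"
                )
            values.append(r)

    all_na = n_na == len(component.elements)
    any_na = n_na > 0
    if all_na and not component.na_eligible:
        # The rating form offers component-wide NA only for eligible components.
        raise ScoringError(
            f"component {component.component_id!r}: all elements rated "
            "not_applicable but the component is not NA-eligible"
        )
    na_hit = all_na if na_mode == "all_elements" else any_na
    if component.na_eligible and na_hit:
        return ComponentAdherence(
            component.component_id, AdherenceStatus.NOT_APPLICABLE, scoreable=False
        )

    status = (
        AdherenceStatus.ADHERED
        if all(v.positive for v in values)
        else AdherenceStatus.NOT_ADHERED
    )
    return ComponentAdherence(component.component_id, status, scoreable=True)


def study_score(
    consensus: RatingSet,
    study: StudyRecord,
    defn: ChecklistDefinition,
    *,
    na_mode: str = "all_elements",
) -> AdherenceResult:
    """Overall adherence score for one study from its consensus ratings.

    The result carries a status for every checklist component: inapplicable
    components are not-applicable and non-scoreable; score-excluded
    components (item 21) are rated descriptively but non-scoreable; the
    score is (adhered scoreable) / (applicable scoreable) components.
    A zero denominator (no applicable components at all) is an error.
    """
    per: list[ComponentAdherence] = []
    for comp in defn.components:
        if not comp.applicability.applies_to(study.study_type):
            per.append(
                ComponentAdherence(
                    comp.component_id,
                    AdherenceStatus.NOT_APPLICABLE,
                    scoreable=False,
                )
            )
            continue
        responses = consensus.component_responses(comp.component_id)
        if comp.excluded_from_score:
            # rate descriptively, but keep out of the score
            ca = component_adherence(
                responses,
                replace(comp, excluded_from_score=False),
                study.study_type,
                na_mode=na_mode,
            )
            per.append(replace(ca, scoreable=False))
            continue
        per.append(
            component_adherence(responses, comp, study.study_type, na_mode=na_mode)
        )

    numerator = sum(
        1
        for ca in per
        if ca.scoreable and ca.status is AdherenceStatus.ADHERED
    )
    denominator = sum(
        1
        for ca in per
        if ca.scoreable and ca.status is not AdherenceStatus.NOT_APPLICABLE
    )
    if denominator == 0:
        raise ScoringError(
            f"study {study.study_id!r}: no applicable components, score undefined"
        )
    return AdherenceResult(
        study_id=study.study_id,
        per_component=tuple(per),
        numerator=numerator,
        denominator=denominator,
    )


def score_corpus(
    consensus_sets: Sequence[RatingSet],
    studies: Sequence[StudyRecord],
    defn: ChecklistDefinition,
    *,
    na_mode: str = "all_elements",
) -> Corpus:
    """Score every study, pairing results with their metadata records."""
    by_id = {rs.study_id: rs for rs in consensus_sets}
    corpus: Corpus = []
    for study in studies:
        if study.study_id not in by_id:
            raise ScoringError(f"no ratings for study {study.study_id!r}")
        corpus.append(
            (study_score(by_id[study.study_id], study, defn, na_mode=na_mode), study)
        )
    return corpus


def item_adherence_table(
    corpus: Corpus,
    defn: ChecklistDefinition,
    subgroup: StudyType | None = None,
) -> list[ItemAdherenceRow]:
    """Per-component adherence counts over a (possibly subgrouped) corpus.

    One row per checklist component, in checklist order, including the
    score-excluded item reported descriptively with ``scoreable=False``.
    ``n_applicable_studies`` counts studies where the component received an
    adhered / not-adhered rating (i.e. was applicable and not rated NA).
    """
    if subgroup is not None:
        corpus = [(res, st) for res, st in corpus if st.study_type is subgroup]
    rows: list[ItemAdherenceRow] = []
    for comp in defn.components:
        n_app = 0
        n_adh = 0
        for res, _ in corpus:
            ca = res.component(comp.component_id)
            if ca.status is AdherenceStatus.NOT_APPLICABLE:
                continue
            n_app += 1
            if ca.status is AdherenceStatus.ADHERED:
                n_adh += 1
        rows.append(
            ItemAdherenceRow(
                component_id=comp.component_id,
                n_adhered=n_adh,
                n_applicable_studies=n_app,
                scoreable=not comp.excluded_from_score,
            )
        )
    return rows


def item_table_frame(rows: Sequence[ItemAdherenceRow]) -> pd.DataFrame:
    """Render item-adherence rows in ``97.6 (41/42)`` style columns."""
    return pd.DataFrame(
        {
            "component_id": [r.component_id for r in rows],
            "n_adhered": [r.n_adhered for r in rows],
            "n_applicable": [r.n_applicable_studies for r in rows],
            "percent": [
                round(float(100 * r.proportion), 1)
                if r.proportion is not None
                else None
                for r in rows
            ],
            "scoreable": [r.scoreable for r in rows],
        }
    )


def corpus_filter(
    corpus: Corpus, predicate: Callable[[StudyRecord], bool]
) -> Corpus:
    """Keep studies whose metadata satisfies the predicate; order is stable."""
    return [(res, st) for res, st in corpus if predicate(st)]


def corpus_scores_frame(corpus: Corpus) -> pd.DataFrame:
    """Study-level table of scores and covariates, ready for modelling."""
    return pd.DataFrame(
        {
            "study_id": [st.study_id for _, st in corpus],
            "study_type": [st.study_type.value for _, st in corpus],
            "publication_year": [st.publication_year for _, st in corpus],
            "journal_category": [st.journal_category for _, st in corpus],
            "impact_factor": [st.impact_factor for _, st in corpus],
            "is_original_article": [st.is_original_article for _, st in corpus],
            "cites_tripod": [st.cites_tripod for _, st in corpus],
            "numerator": [res.numerator for res, _ in corpus],
            "denominator": [res.denominator for res, _ in corpus],
            "score": [res.score_float for res, _ in corpus],
        }
    )
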