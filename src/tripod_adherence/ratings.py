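"""Element-level ratings, study metadata, disagreements and consensus.

Ratings live in long format, one row per (study, reviewer, component,
element), with response tokens ``yes`` / ``no`` / ``referenced`` /
``not_applicable``.  ``referenced`` means the requested information is in a
cited publication and counts as adherence-positive; ``not_applicable`` is
valid only for elements that allow it.  Consensus is an explicit process:
disagreements between reviewers are surfaced, then resolved either by an
adjudication table (mirroring consensus meetings plus referees) or,
optionally, by strict majority vote.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .checklist import ChecklistDefinition, StudyType

__all__ = [
    "Response",
    "StudyRecord",
    "RatingSet",
    "Disagreement",
    "RatingsError",
    "JOURNAL_CATEGORIES",
    "CONSENSUS_REVIEWER",
    "read_ratings",
    "write_ratings",
    "read_studies",
    "write_studies",
    "find_disagreements",
    "apply_consensus",
]

CONSENSUS_REVIEWER = "consensus"

#: Journal Citation Reports subject categories used as the default
#: categorical covariate; journals outside JCR map to "Other".
JOURNAL_CATEGORIES = (
    "Dermatology",
    "Oncology",
    "Medicine General & Internal",
    "Multidisciplinary Sciences",
    "Public Environmental & Occupational Health",
    "Other",
)


class Response(str, Enum):
    YES = "yes"
    NO = "no"
    REFERENCED = "referenced"
    NOT_APPLICABLE = "not_applicable"

    @property
    def positive(self) -> bool:
        """Whether the response counts toward adherence."""
        return self in (Response.YES, Response.REFERENCED)


class RatingsError(ValueError):
    """A ratings or metadata table violates the schema or the checklist."""


@dataclass(frozen=True)
class StudyRecord:
    """Per-study metadata used for subgrouping and regression covariates."""

    study_id: str
    study_type: StudyType
    publication_year: int
    journal_category: str
    impact_factor: float
    is_original_article: bool = True
    cites_tripod: bool = False

    def __post_init__(self) -> None:
        if not 1900 <= self.publication_year <= 2100:
            raise RatingsError(
                f"study {self.study_id!r}: publication_year "
                f"{self.publication_year} outside 1900-2100"
            )
        if self.impact_factor < 0:
            raise RatingsError(
                f"study {self.study_id!r}: negative impact_factor"
            )


@dataclass(frozen=True)
class RatingSet:
    """All element responses for one study from one reviewer (or consensus)."""

    study_id: str
    reviewer_id: str
    responses: dict[tuple[str, str], Response]

    @property
    def is_consensus(self) -> bool:
        return self.reviewer_id == CONSENSUS_REVIEWER

    def component_responses(self, component_id: str) -> dict[str, Response]:
        """Responses for one component, keyed by element id."""
        return {
            eid: r
            for (cid, eid), r in self.responses.items()
            if cid == component_id
        }


@dataclass(frozen=True)
class Disagreement:
    """Distinct responses given by different reviewers to one element."""

    study_id: str
    component_id: str
    element_id: str
    responses: dict[Response, tuple[str, ...]]  # response -> reviewer ids

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.study_id, self.component_id, self.element_id)


RATINGS_COLUMNS = ["study_id", "reviewer_id", "component_id", "element_id", "response"]
STUDIES_COLUMNS = [
    "study_id",
    "study_type",
    "publication_year",
    "journal_category",
    "impact_factor",
    "is_original_article",
    "cites_tripod",
]


def _check_response_allowed(
    defn: ChecklistDefinition, cid: str, eid: str, response: Response, where: str
) -> None:
    if cid not in defn:
        raise RatingsError(f"{where}: unknown component {cid!r}")
    comp = defn.component(cid)
    try:
        elem = comp.element(eid)
    except KeyError:
        raise RatingsError(
            f"{where}: unknown element {eid!r} of component {cid!r}"
        ) from None
    if response is Response.REFERENCED and not elem.referenced_allowed:
        raise RatingsError(
            f"{where}: 'referenced' not an allowed response for element "
            f"{eid!r} of component {cid!r}"
        )
    if response is Response.NOT_APPLICABLE and not elem.na_allowed:
        raise RatingsError(
            f"{where}: 'not_applicable' not an allowed response for element "
            f"{eid!r} of component {cid!r}"
        )


def read_ratings(
    path: str | Path, defn: ChecklistDefinition | None = None
) -> list[RatingSet]:
    """Read long-format ratings from CSV into per-(study, reviewer) sets.

    Columns: ``study_id,reviewer_id,component_id,element_id,response``.
    Unknown response tokens raise :class:`RatingsError` with the 1-based data
    row number; when a checklist definition is supplied, component/element
    keys and response options are validated against it.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsError(f"{path}: missing columns {missing}")
    sets: dict[tuple[str, str], dict[tuple[str, str], Response]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            response = Response(row.response)
        except ValueError:
            raise RatingsError(
                f"{path}: row {i}: unknown response token {row.response!r}"
            ) from None
        if defn is not None:
            _check_response_allowed(
                defn, row.component_id, row.element_id, response,
                f"{path}: row {i}",
            )
        key = (row.study_id, row.reviewer_id)
        sets.setdefault(key, {})[(row.component_id, row.element_id)] = response
    return [
        RatingSet(study_id=s, reviewer_id=r, responses=resp)
        for (s, r), resp in sets.items()
    ]


def ratings_frame(rating_sets: Iterable[RatingSet]) -> pd.DataFrame:
    rows = [
        (rs.study_id, rs.reviewer_id, cid, eid, r.value)
        for rs in rating_sets
        for (cid, eid), r in rs.responses.items()
    ]
    return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


def write_ratings(rating_sets: Iterable[RatingSet], path: str | Path) -> None:
    ratings_frame(rating_sets).to_csv(path, index=False)


def read_studies(
    path: str | Path, categories: Sequence[str] | None = JOURNAL_CATEGORIES
) -> list[StudyRecord]:
    """Read study metadata from CSV; ``categories=None`` skips the category check."""
    df = pd.read_csv(path)
    missing = [c for c in STUDIES_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsError(f"{path}: missing columns {missing}")
    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.study_id)
        if sid in seen:
            raise RatingsError(f"{path}: row {i}: duplicate study_id {sid!r}")
        seen.add(sid)
        try:
            stype = StudyType(row.study_type)
        except ValueError:
            raise RatingsError(
                f"{path}: row {i}: unknown study_type {row.study_type!r}"
            ) from None
        cat = str(row.journal_category)
        if categories is not None and cat not in categories:
            raise RatingsError(
                f"{path}: row {i}: unknown journal_category {cat!r}"
            )
        records.append(
            StudyRecord(
                study_id=sid,
                study_type=stype,
                publication_year=int(row.publication_year),
                journal_category=cat,
                impact_factor=float(row.impact_factor),
                is_original_article=_to_bool(row.is_original_article),
                cites_tripod=_to_bool(row.cites_tripod),
            )
        )
    return records


def _to_bool(v) -> bool:
    if isinstance(v, str):
        lv = v.strip().lower()
        if lv in ("true", "1", "yes"):
            return True
        if lv in ("false", "0", "no"):
            return False
        raise RatingsError(f"cannot interpret {v!r} as a boolean")
    return bool(v)


def studies_frame(studies: Iterable[StudyRecord]) -> pd.DataFrame:
    rows = [
        (
            s.study_id,
            s.study_type.value,
            s.publication_year,
            s.journal_category,
            s.impact_factor,
            s.is_original_article,
            s.cites_tripod,
        )
        for s in studies
    ]
    return pd.DataFrame(rows, columns=STUDIES_COLUMNS)


def write_studies(studies: Iterable[StudyRecord], path: str | Path) -> None:
    studies_frame(studies).to_csv(path, index=False)


def find_disagreements(
    ratings: Sequence[RatingSet], defn: ChecklistDefinition | None = None
) -> list[Disagreement]:
    """List every (study, component, element) with >= 2 distinct responses.

    Any pair of distinct responses is flagged — including pairs such as
    ``yes`` vs ``referenced`` that are both adherence-positive — since the
    resolution rule is left to adjudication.  Output is sorted by
    (study_id, component_id, element_id).
    """
    by_study: dict[str, list[RatingSet]] = {}
    for rs in ratings:
        if rs.is_consensus:
            continue
        by_study.setdefault(rs.study_id, []).append(rs)

    out: list[Disagreement] = []
    for sid in sorted(by_study):
        votes: dict[tuple[str, str], dict[Response, list[str]]] = {}
        for rs in by_study[sid]:
            for key, resp in rs.responses.items():
                votes.setdefault(key, {}).setdefault(resp, []).append(
                    rs.reviewer_id
                )
        for (cid, eid) in sorted(votes):
            by_resp = votes[(cid, eid)]
            if len(by_resp) >= 2:
                out.append(
                    Disagreement(
                        study_id=sid,
                        component_id=cid,
                        element_id=eid,
                        responses={
                            r: tuple(sorted(revs))
                            for r, revs in by_resp.items()
                        },
                    )
                )
    return out


def apply_consensus(
    ratings: Sequence[RatingSet],
    adjudications: Mapping[tuple[str, str, str], Response] | None = None,
    *,
    majority: bool = False,
) -> list[RatingSet]:
    """Collapse multi-reviewer ratings into one consensus set per study.

    Unanimous elements pass through.  Disagreeing elements take the value
    from ``adjudications`` (keyed by (study_id, component_id, element_id));
    with ``majority=True``, elements without an adjudication entry are
    resolved by strict majority instead, and an exact tie is an error.  Any
    remaining unresolved disagreement raises :class:`RatingsError`
    enumerating the unresolved triples — there is no silent default.

    Idempotent: applied to its own output it returns the same consensus.
    """
    adjudications = dict(adjudications or {})
    by_study: dict[str, list[RatingSet]] = {}
    for rs in ratings:
        by_study.setdefault(rs.study_id, []).append(rs)

    out: list[RatingSet] = []
    unresolved: list[tuple[str, str, str]] = []
    for sid in sorted(by_study):
        votes: dict[tuple[str, str], Counter] = {}
        for rs in by_study[sid]:
            for key, resp in rs.responses.items():
                votes.setdefault(key, Counter())[resp] += 1
        consensus: dict[tuple[str, str], Response] = {}
        for (cid, eid) in sorted(votes):
            counts = votes[(cid, eid)]
            if len(counts) == 1:
                consensus[(cid, eid)] = next(iter(counts))
                continue
            adj = adjudications.get((sid, cid, eid))
            if adj is not None:
                consensus[(cid, eid)] = Response(adj)
                continue
            if majority:
                (top, n1), (_, n2) = counts.most_common(2)
                if n1 > n2:
                    consensus[(cid, eid)] = top
                    continue
                raise RatingsError(
                    f"majority consensus tied on ({sid!r}, {cid!r}, {eid!r}); "
                    "provide an adjudication"
                )
            unresolved.append((sid, cid, eid))
        out.append(
            RatingSet(
                study_id=sid,
                reviewer_id=CONSENSUS_REVIEWER,
                responses=consensus,
            )
        )
    if unresolved:
        raise RatingsError(
            "unresolved disagreements without adjudication: "
            + ", ".join(map(repr, unresolved))
        )
    return out
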