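"""Machine-readable reporting checklist: structure, validation and applicability.

A checklist (the shipped instance is TRIPOD, the reporting guideline for
multivariable prediction-model studies) is a flat, ordered list of
*components* — numbered items, optionally split into lettered subitems such
as ``10c`` — each holding one or more *elements*, the individually rated
requirement clauses.  Components carry the study-type applicability marks
that drive the adherence-score denominator: some apply only when a model is
developed, some only when one is validated, and a few may be rated
"not applicable" by reviewers, which removes them from the denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
__all__ = [
    "StudyType",
    "Applicability",
    "Element",
    "Component",
    "ChecklistDefinition",
    "ChecklistError",
    "load_checklist",
    "write_checklist",
    "load_tripod",
    "scoreable_components",
]


class StudyType(str, Enum):
    """The kinds of prediction-model study a checklist distinguishes."""

    DEVELOPMENT = "development"
    VALIDATION = "validation"
    DEVELOPMENT_AND_VALIDATION = "development_and_validation"


class Applicability(str, Enum):
    """Which study types a component is rated for."""

    DEVELOPMENT_ONLY = "development_only"
    VALIDATION_ONLY = "validation_only"
    BOTH = "both"

    def applies_to(self, study_type: StudyType) -> bool:
        if self is Applicability.BOTH:
            return True
        if study_type is StudyType.DEVELOPMENT_AND_VALIDATION:
            return True
        if study_type is StudyType.DEVELOPMENT:
            return self is Applicability.DEVELOPMENT_ONLY
        return self is Applicability.VALIDATION_ONLY


class ChecklistError(ValueError):
    """A checklist file violates the schema or its structural invariants."""


@dataclass(frozen=True)
class Element:
    """One individually rated requirement clause within a component."""

    element_id: str
    text: str
    referenced_allowed: bool = False
    na_allowed: bool = False


@dataclass(frozen=True)
class Component:
    """An item or lettered subitem that receives an adherence rating."""

    component_id: str
    item_number: int
    subitem_letter: str | None
    elements: tuple[Element, ...]
    applicability: Applicability = Applicability.BOTH
    na_eligible: bool = False
    excluded_from_score: bool = False

    @property
    def is_subitem(self) -> bool:
        return self.subitem_letter is not None

    def element(self, element_id: str) -> Element:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(
            f"component {self.component_id!r} has no element {element_id!r}"
        )


@dataclass(frozen=True)
class ChecklistDefinition:
    """An ordered collection of components forming one checklist version."""

    name: str
    version: str
    components: tuple[Component, ...]
    _index: dict[str, Component] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {c.component_id: c for c in self.components}
        )

    @property
    def item_numbers(self) -> tuple[int, ...]:
        """Distinct item numbers, in order of first appearance."""
        seen: dict[int, None] = {}
        for c in self.components:
            seen.setdefault(c.item_number, None)
        return tuple(seen)

    @property
    def n_items(self) -> int:
        return len(self.item_numbers)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_subitems(self) -> int:
        return sum(c.is_subitem for c in self.components)

    def component(self, component_id: str) -> Component:
        try:
            return self._index[component_id]
        except KeyError:
            raise KeyError(
                f"checklist {self.name!r} has no component {component_id!r}"
            ) from None

    def __contains__(self, component_id: str) -> bool:
        return component_id in self._index

    def __iter__(self):
        return iter(self.components)


def _validate(defn: ChecklistDefinition) -> None:
    problems: list[str] = []
    seen: set[str] = set()
    for c in defn.components:
        if not c.component_id:
            problems.append("empty component_id")
        if c.component_id in seen:
            problems.append(f"duplicate component_id {c.component_id!r}")
        seen.add(c.component_id)
        if not 1 <= c.item_number <= 99:
            problems.append(
                f"component {c.component_id!r}: item_number {c.item_number} out of range"
            )
        if not c.elements:
            problems.append(f"component {c.component_id!r}: no elements")
        eids = [e.element_id for e in c.elements]
        if len(set(eids)) != len(eids):
            problems.append(
                f"component {c.component_id!r}: duplicate element ids"
            )
        if any(not e.element_id for e in c.elements):
            problems.append(f"component {c.component_id!r}: empty element_id")
    if problems:
        raise ChecklistError(
            "invalid checklist definition: " + "; ".join(problems)
        )


def _component_from_dict(d: dict) -> Component:
    try:
        applicability = Applicability(d.get("applicability", "both"))
    except ValueError:
        raise ChecklistError(
            f"component {d.get('component_id')!r}: unknown applicability "
            f"{d.get('applicability')!r}"
        ) from None
    elements = tuple(
        Element(
            element_id=str(e["element_id"]),
            text=str(e.get("text", "")),
            referenced_allowed=bool(e.get("referenced_allowed", False)),
            na_allowed=bool(e.get("na_allowed", False)),
        )
        for e in d.get("elements", [])
    )
    return Component(
        component_id=str(d["component_id"]),
        item_number=int(d["item_number"]),
        subitem_letter=d.get("subitem_letter") or None,
        elements=elements,
        applicability=applicability,
        na_eligible=bool(d.get("na_eligible", False)),
        excluded_from_score=bool(d.get("excluded_from_score", False)),
    )


def load_checklist(path: str | Path) -> ChecklistDefinition:
    """Load and validate a checklist definition from a JSON file.

    The file is a UTF-8 JSON object with keys ``name``, ``version`` and
    ``components``; each component carries its id, item number, optional
    subitem letter, applicability mark, NA eligibility, score-exclusion flag
    and an ordered element list.  Structural violations (missing or
    duplicate ids, empty element lists, unknown applicability values) raise
    :class:`ChecklistError` naming the offending component.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ChecklistError(f"{path}: not valid JSON: {exc}") from exc
    return checklist_from_dict(doc)


def checklist_from_dict(doc: dict) -> ChecklistDefinition:
    """Build a validated :class:`ChecklistDefinition` from a parsed mapping."""
    if not isinstance(doc, dict) or "components" not in doc:
        raise ChecklistError("checklist document must map 'components' to a list")
    try:
        comps = tuple(_component_from_dict(d) for d in doc["components"])
    except (KeyError, TypeError) as exc:
        raise ChecklistError(f"malformed component entry: {exc}") from exc
    defn = ChecklistDefinition(
        name=str(doc.get("name", "")),
        version=str(doc.get("version", "")),
        components=comps,
    )
    _validate(defn)
    return defn


def checklist_to_dict(defn: ChecklistDefinition) -> dict:
    return {
        "name": defn.name,
        "version": defn.version,
        "components": [
            {
                "component_id": c.component_id,
                "item_number": c.item_number,
                "subitem_letter": c.subitem_letter,
                "applicability": c.applicability.value,
                "na_eligible": c.na_eligible,
                "excluded_from_score": c.excluded_from_score,
                "elements": [
                    {
                        "element_id": e.element_id,
                        "text": e.text,
                        "referenced_allowed": e.referenced_allowed,
                        "na_allowed": e.na_allowed,
                    }
                    for e in c.elements
                ],
            }
            for c in defn.components
        ],
    }


def write_checklist(defn: ChecklistDefinition, path: str | Path) -> None:
    """Serialise a checklist back to JSON; round-trips with ``load_checklist``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(checklist_to_dict(defn), fh, indent=1)
        fh.write("\n")


def load_tripod() -> ChecklistDefinition:
    """Return the shipped TRIPOD checklist (22 items, 37 components)."""
    ref = resources.files("tripod_adherence.data").joinpath("tripod.json")
    return checklist_from_dict(json.loads(ref.read_text(encoding="utf-8")))


def scoreable_components(
    defn: ChecklistDefinition, study_type: StudyType
) -> list[Component]:
    """Components entering the adherence score for the given study type.

    Drops score-excluded components (item 21 in TRIPOD: availability of
    supplementary material) and those whose applicability mark conflicts
    with the study type.  Order is preserved.  For TRIPOD this yields 36
    components for a combined development-and-validation study and 30 for a
    validation-only study.
    """
    return [
        c
        for c in defn.components
        if not c.excluded_from_score and c.applicability.applies_to(study_type)
    ]
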