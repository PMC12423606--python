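"""Document data model: bundle, composition header, sections, entries, actors.

The unit of exchange is an :class:`NCDDocument` — an ordered document bundle
whose first entry is the :class:`CompositionHeader`.  The header carries three
extensions (export period, export date, DIN metadata), links the subject, an
optional practitioner and any related persons, and exactly three data
sections: clinical, game, and lifestyle.

Every construction operation is pure: documents are immutable values and each
operation returns a new document, leaving its input untouched.  Structural
equality therefore means "same document".

Element obligations follow a three-way scheme from the underlying data-model
legend: M (mandatory), O (optional), and D (dependent-mandatory — mandatory
only for application archetypes whose risk factor or produced data covers the
element).  The element table is a replaceable packaged data file; obligations
are resolved per archetype by :func:`resolve_obligations`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from functools import lru_cache
from importlib import resources
from typing import Optional, Union

from . import terminology
from .errors import (
    CodeCategoryMismatchError,
    DuplicatePractitionerError,
    InvalidPeriodError,
    UnknownArchetypeError,
)

CATEGORIES = ("clinical", "game", "lifestyle")

#: Profile tags minted by this guide.
NCD_BUNDLE_PROFILE = "ncd-bundle"
NCD_PATIENT_PROFILE = "ncd-patient"
NCD_PRACTITIONER_PROFILE = "ncd-practitioner"
NCD_RELATED_PERSON_PROFILE = "ncd-related-person"

RISK_FACTORS = ("smoking", "nutrition", "mental-health", "hyperglycemia")
APP_TYPES = ("serious game", "gamified app", "gamified web application", "modification")


# ---------------------------------------------------------------------------
# value payloads


@dataclass(frozen=True)
class Quantity:
    """A measured quantity with its unit (e.g. 112.0 'mg/dL')."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("quantity payloads must carry a unit string")


@dataclass(frozen=True)
class Score:
    """A non-negative integer score (points, ordinal scales, questionnaires)."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("score payloads must be non-negative")


@dataclass(frozen=True)
class Text:
    value: str


@dataclass(frozen=True)
class Coded:
    token: str


EntryValue = Union[Quantity, Score, Text, Coded]


# ---------------------------------------------------------------------------
# period / metadata


@dataclass(frozen=True)
class Period:
    """A timezone-aware time interval with start <= end."""

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        for dt in (self.start, self.end):
            if dt.tzinfo is None:
                raise ValueError("period bounds must be timezone-aware")
        if self.start > self.end:
            raise InvalidPeriodError(f"period start {self.start} is after end {self.end}")

    def contains(self, dt: datetime) -> bool:
        return self.start <= dt <= self.end


@dataclass(frozen=True)
class DINMetadata:
    """DIN serious-game descriptive metadata, carried structurally.

    The guide's document shape transports this as a single free-text
    extension; :meth:`render_text` is that canonical rendering, derived from
    the structured elements ("key=value" lines in element order).
    """

    declared_level: int
    elements: tuple[tuple[str, str], ...] = ()
    raw_text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.declared_level not in (1, 2, 3):
            raise ValueError(f"DIN declared_level must be 1-3, got {self.declared_level!r}")

    @property
    def elements_map(self) -> dict[str, str]:
        return dict(self.elements)

    def render_text(self) -> str:
        if self.elements:
            body = "\n".join(f"{k}={v}" for k, v in self.elements)
            return f"din-level={self.declared_level}\n{body}"
        return self.raw_text or f"din-level={self.declared_level}"

    @classmethod
    def from_text(cls, text: str) -> "DINMetadata":
        level = 1
        pairs: list[tuple[str, str]] = []
        for line in text.splitlines():
            if "=" not in line:
                continue
            key, value = line.split("=", 1)
            if key == "din-level":
                level = int(value)
            else:
                pairs.append((key, value))
        return cls(declared_level=level, elements=tuple(pairs), raw_text=None)


# ---------------------------------------------------------------------------
# actors


@dataclass(frozen=True)
class PatientRecord:
    resource_id: str
    pseudonym: str
    birth_year: Optional[int] = None
    profile_tag: str = NCD_PATIENT_PROFILE


@dataclass(frozen=True)
class PractitionerRecord:
    resource_id: str
    pseudonym: str
    profile_tag: str = NCD_PRACTITIONER_PROFILE


@dataclass(frozen=True)
class RelatedPersonRecord:
    resource_id: str
    pseudonym: str
    relationship: str = "related"
    profile_tag: str = NCD_RELATED_PERSON_PROFILE


# ---------------------------------------------------------------------------
# entries and sections


@dataclass(frozen=True)
class Entry:
    """One recorded datum: a coded, timed, typed observation-like value."""

    entry_id: str
    category: str  # clinical | game | lifestyle
    code: tuple[str, str]  # (system URI, code token)
    effective_time: Union[datetime, Period]
    value: EntryValue
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown entry category {self.category!r}")
        if isinstance(self.effective_time, datetime) and self.effective_time.tzinfo is None:
            raise ValueError("entry timestamps must be timezone-aware")


@dataclass(frozen=True)
class SectionComposition:
    """One of the three data sections; holds references to entry ids."""

    kind: str  # clinical | game | lifestyle
    entry_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in CATEGORIES:
            raise ValueError(f"unknown section kind {self.kind!r}")


@dataclass(frozen=True)
class CompositionHeader:
    """The composition: three extensions, actor links, three sections."""

    export_period: Period
    export_date: datetime
    din_metadata: DINMetadata
    subject_ref: str
    sections: tuple[SectionComposition, ...]
    practitioner_ref: Optional[str] = None
    related_person_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.export_date.tzinfo is None:
            raise ValueError("export_date must be timezone-aware")
        kinds = [s.kind for s in self.sections]
        if sorted(kinds) != sorted(CATEGORIES) or len(kinds) != 3:
            raise ValueError("header must carry exactly the three distinct sections")

    def section(self, kind: str) -> SectionComposition:
        for s in self.sections:
            if s.kind == kind:
                return s
        raise KeyError(kind)


Resource = Union[
    CompositionHeader, PatientRecord, PractitionerRecord, RelatedPersonRecord, Entry
]


@dataclass(frozen=True)
class NCDDocument:
    """The document bundle; the first entry is the composition header.

    A bundle whose header is displaced (not first) is representable so that
    validation can report it; a bundle with no header at all is not a
    document and cannot be traversed.
    """

    document_id: str
    entries: tuple[Resource, ...]
    profile_tag: str = NCD_BUNDLE_PROFILE
    extras: tuple[tuple[str, str], ...] = ()  # opaque side-channel for round-trips

    def __post_init__(self) -> None:
        if not self.document_id:
            raise ValueError("document_id must be non-empty")
        if not any(isinstance(r, CompositionHeader) for r in self.entries):
            raise ValueError("document must contain a composition header")

    @property
    def header(self) -> CompositionHeader:
        """The (first) composition header, wherever it sits in the bundle."""
        for res in self.entries:
            if isinstance(res, CompositionHeader):
                return res
        raise AssertionError("unreachable: checked at construction")

    @property
    def header_first(self) -> bool:
        return isinstance(self.entries[0], CompositionHeader)

    def resource_ids(self) -> set[str]:
        out: set[str] = set()
        for res in self.entries:
            if isinstance(res, CompositionHeader):
                continue
            out.add(res.entry_id if isinstance(res, Entry) else res.resource_id)
        return out

    def find_entry(self, entry_id: str) -> Optional[Entry]:
        for res in self.entries:
            if isinstance(res, Entry) and res.entry_id == entry_id:
                return res
        return None

    def data_entries(self, category: Optional[str] = None) -> tuple[Entry, ...]:
        out = [r for r in self.entries if isinstance(r, Entry)]
        if category is not None:
            out = [e for e in out if e.category == category]
        return tuple(out)

    def references(self) -> tuple[str, ...]:
        """All references the composition makes, in document order."""
        hdr = self.header
        refs = [hdr.subject_ref]
        if hdr.practitioner_ref is not None:
            refs.append(hdr.practitioner_ref)
        refs.extend(hdr.related_person_refs)
        for sec in hdr.sections:
            refs.extend(sec.entry_refs)
        return tuple(refs)

    def is_closed(self) -> bool:
        """True iff every composition reference resolves inside the bundle."""
        ids = self.resource_ids()
        return all(ref in ids for ref in self.references())


# ---------------------------------------------------------------------------
# archetypes and obligations


@dataclass(frozen=True)
class AppArchetype:
    """One analyzed application archetype (G1-G8) driving obligations/synthesis."""

    archetype_id: str
    name: str
    app_type: str
    platform: str
    main_risk_factor: str
    produced_elements: tuple[str, ...]
    best_effort: bool = False

    def __post_init__(self) -> None:
        if self.main_risk_factor not in RISK_FACTORS:
            raise ValueError(f"unknown risk factor {self.main_risk_factor!r}")
        if self.app_type not in APP_TYPES:
            raise ValueError(f"unknown app type {self.app_type!r}")


@dataclass(frozen=True)
class ElementRule:
    """One row of the packaged element-obligation table."""

    path: str
    obligation: str  # M | O | D
    risk_factor: str = ""  # activates a D row when it matches the archetype
    category: str = ""  # entry rows: clinical | game | lifestyle
    code_system: str = ""  # 'loinc' or a packaged local system id
    code: str = ""

    def code_pair(self, canonical_base: str = terminology.DEFAULT_CANONICAL_BASE) -> tuple[str, str]:
        """(system URI, code token) this entry path is coded with."""
        if self.code_system == "loinc":
            return (terminology.LOINC_URI, self.code)
        if self.code_system == "snomed-ct":
            return (terminology.SNOMED_CT_URI, self.code)
        return (terminology.canonical_uri(self.code_system, canonical_base), self.code)


@lru_cache(maxsize=None)
def element_table() -> tuple[ElementRule, ...]:
    """The packaged element-obligation table (replaceable data file)."""
    ref = resources.files("ncdkit.data").joinpath("element_obligations.tsv")
    rules = []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rules.append(
                ElementRule(
                    path=row["path"],
                    obligation=row["obligation"],
                    risk_factor=row.get("risk_factor") or "",
                    category=row.get("category") or "",
                    code_system=row.get("code_system") or "",
                    code=row.get("code") or "",
                )
            )
    return tuple(rules)


def element_rule(path: str) -> ElementRule:
    for rule in element_table():
        if rule.path == path:
            return rule
    raise KeyError(f"no element rule for path {path!r}")


@dataclass(frozen=True)
class ObligationSet:
    """Resolved obligations: element path -> M | O | D-active | D-inactive.

    During validation D-active behaves exactly as M and D-inactive as O.
    """

    obligations: tuple[tuple[str, str], ...]

    def as_dict(self) -> dict[str, str]:
        return dict(self.obligations)

    def mandatory_paths(self) -> tuple[str, ...]:
        return tuple(p for p, o in self.obligations if o in ("M", "D-active"))


def resolve_obligations(archetype: Union[AppArchetype, str]) -> ObligationSet:
    """Resolve the packaged element table against one application archetype.

    M and O rows pass through unchanged.  A D row becomes D-active when the
    archetype's main risk factor matches the row's activating risk factor, or
    when the archetype explicitly lists the element among its produced
    elements; otherwise it stays D-inactive.

    Accepts an archetype id (G1-G8) for convenience; unknown ids raise
    :class:`UnknownArchetypeError`.
    """
    if isinstance(archetype, str):
        from .synth import archetype_registry  # local import: synth depends on model

        registry = archetype_registry()
        if archetype not in registry.archetypes_map:
            raise UnknownArchetypeError(f"unknown archetype id {archetype!r}")
        archetype = registry.archetypes_map[archetype]
    produced = set(archetype.produced_elements)
    resolved: list[tuple[str, str]] = []
    for rule in element_table():
        if rule.obligation != "D":
            resolved.append((rule.path, rule.obligation))
        elif rule.risk_factor == archetype.main_risk_factor or rule.path in produced:
            resolved.append((rule.path, "D-active"))
        else:
            resolved.append((rule.path, "D-inactive"))
    return ObligationSet(obligations=tuple(resolved))


# ---------------------------------------------------------------------------
# construction operations (pure)


def new_document(
    subject: PatientRecord,
    period: Period,
    export_date: datetime,
    din: DINMetadata,
    document_id: Optional[str] = None,
) -> NCDDocument:
    """Create a minimal conformant document: header + subject, empty sections.

    The three composition extensions (export period, export date, DIN
    metadata) are always populated and the three sections are created empty.
    The default document id is derived from the subject so that equal inputs
    yield structurally equal documents.
    """
    header = CompositionHeader(
        export_period=period,
        export_date=export_date,
        din_metadata=din,
        subject_ref=subject.resource_id,
        sections=tuple(SectionComposition(kind=k) for k in CATEGORIES),
    )
    return NCDDocument(
        document_id=document_id or f"doc-{subject.resource_id}",
        entries=(header, subject),
    )


def _category_system_uri(category: str, canonical_base: str) -> Optional[str]:
    if category == "game":
        return terminology.canonical_uri("ncd-gamedata", canonical_base)
    if category == "lifestyle":
        return terminology.canonical_uri("ncd-lifestyle", canonical_base)
    return None


def add_entry(
    doc: NCDDocument,
    entry: Entry,
    canonical_base: str = terminology.DEFAULT_CANONICAL_BASE,
) -> NCDDocument:
    """Append an entry to the bundle and to its matching section.

    Game and lifestyle entries must be coded from their category's code
    system (``ncd-gamedata`` / ``ncd-lifestyle``); anything else raises
    :class:`CodeCategoryMismatchError`.  Clinical entries may use any
    terminology.  The input document is not modified.
    """
    required_uri = _category_system_uri(entry.category, canonical_base)
    if required_uri is not None and entry.code[0] != required_uri:
        raise CodeCategoryMismatchError(
            f"{entry.category} entry {entry.entry_id!r} coded from {entry.code[0]!r}, "
            f"expected {required_uri!r}"
        )
    hdr = doc.header
    sections = tuple(
        replace(s, entry_refs=s.entry_refs + (entry.entry_id,))
        if s.kind == entry.category
        else s
        for s in hdr.sections
    )
    new_header = replace(hdr, sections=sections)
    return replace(doc, entries=(new_header,) + doc.entries[1:] + (entry,))


def attach_practitioner(doc: NCDDocument, pract: PractitionerRecord) -> NCDDocument:
    """Link an attending practitioner (cardinality 0..1).

    Conformance of the practitioner's profile tag is checked by validation,
    not here; attaching an untagged record succeeds and is reported later.
    """
    if doc.header.practitioner_ref is not None:
        raise DuplicatePractitionerError(
            f"document {doc.document_id!r} already links practitioner "
            f"{doc.header.practitioner_ref!r}"
        )
    new_header = replace(doc.header, practitioner_ref=pract.resource_id)
    return replace(doc, entries=(new_header,) + doc.entries[1:] + (pract,))


def attach_related_person(doc: NCDDocument, person: RelatedPersonRecord) -> NCDDocument:
    """Link a related person (cardinality 0..*)."""
    new_header = replace(
        doc.header,
        related_person_refs=doc.header.related_person_refs + (person.resource_id,),
    )
    return replace(doc, entries=(new_header,) + doc.entries[1:] + (person,))


def entry_for_path(
    path: str,
    entry_id: str,
    effective_time: Union[datetime, Period],
    value: EntryValue,
    note: Optional[str] = None,
    canonical_base: str = terminology.DEFAULT_CANONICAL_BASE,
) -> Entry:
    """Build an entry coded per the packaged element table row for ``path``."""
    rule = element_rule(path)
    if not rule.category:
        raise KeyError(f"element path {path!r} is not an entry path")
    return Entry(
        entry_id=entry_id,
        category=rule.category,
        code=rule.code_pair(canonical_base),
        effective_time=effective_time,
        value=value,
        note=note,
    )
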