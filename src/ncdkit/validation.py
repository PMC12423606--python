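"""Rule-based conformance checking of NCD documents.

The validator checks the document against the guide's own rule set — bundle
structure, reference closure, element obligations, value-set bindings,
reference-target profile restrictions, section/category agreement, and DIN
metadata levels.  It is not a general FHIR structural validator.

All findings are reported, never thrown; only input that cannot be traversed
at all raises :class:`~ncdkit.errors.MalformedDocumentError`.  Reports are
deterministic: issues are ordered by (path, code), and equal inputs produce
byte-identical text renderings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from . import terminology
from .errors import InvalidLevelError, MalformedDocumentError, UnknownIssueCodeError
from .model import (
    NCD_PRACTITIONER_PROFILE,
    CompositionHeader,
    DINMetadata,
    Entry,
    NCDDocument,
    ObligationSet,
    PractitionerRecord,
    element_table,
)

SEVERITIES = ("error", "warning", "info")

#: The closed issue catalogue: code -> (severity, explanation incl. rule source).
ISSUE_CATALOGUE: dict[str, tuple[str, str]] = {
    "DOC_FIRST_ENTRY_NOT_COMPOSITION": (
        "error",
        "A document bundle must start with the composition resource; every other "
        "resource follows it and is referenced from it.",
    ),
    "UNRESOLVED_REFERENCE": (
        "error",
        "Every reference made by the composition (subject, practitioner, related "
        "persons, section entries) must resolve to exactly one resource inside the "
        "same bundle; documents are self-contained units of exchange.",
    ),
    "MISSING_MANDATORY_ELEMENT": (
        "error",
        "An element marked mandatory (M) — or dependent-mandatory (D) and activated "
        "for the application archetype at hand — is absent from the document.",
    ),
    "CODE_NOT_IN_VALUESET": (
        "error",
        "Game and lifestyle entries must be coded from their category's code system "
        "value set (NCD Gamedata / NCD Lifestyle data); this code is not a member.",
    ),
    "REFERENCE_PROFILE_VIOLATION": (
        "error",
        "The attending-practitioner link is restricted to records conforming to the "
        "NCD Practitioner profile; the linked record carries no such profile tag.",
    ),
    "SECTION_CATEGORY_MISMATCH": (
        "error",
        "Each of the three data sections (clinical, game, lifestyle) may only "
        "reference entries of its own category.",
    ),
    "DIN_LEVEL_UNMET": (
        "error",
        "The DIN serious-game metadata must contain every descriptive element of the "
        "level being checked; level 1 (core) is the minimum to support.",
    ),
    "DIN_LEVEL_PREFERRED": (
        "info",
        "Compliance with DIN levels 1 and 2 is preferred though only level 1 is "
        "required; a supplementary level-2 element is absent.",
    ),
    "UNKNOWN_EXTENSION": (
        "info",
        "An extension not defined by this guide was encountered and ignored "
        "(open-world reading); it is preserved on round-trip.",
    ),
}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str
    code: str
    path: str
    message: str

    def __post_init__(self) -> None:
        if self.code not in ISSUE_CATALOGUE:
            raise ValueError(f"issue code {self.code!r} not in catalogue")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def conformant(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    def to_text(self) -> str:
        """Line-oriented rendering, stable across runs."""
        lines = [f"conformant: {'yes' if self.conformant else 'no'}"]
        for issue in self.issues:
            lines.append(f"{issue.severity}\t{issue.code}\t{issue.path}\t{issue.message}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "conformant": self.conformant,
                "issues": [
                    {"severity": i.severity, "code": i.code, "path": i.path, "message": i.message}
                    for i in self.issues
                ],
            },
            indent=2,
        )


def _issue(code: str, path: str, message: str) -> ValidationIssue:
    severity = ISSUE_CATALOGUE[code][0]
    return ValidationIssue(severity=severity, code=code, path=path, message=message)


def _finalize(issues: list[ValidationIssue]) -> ValidationReport:
    ordered = tuple(sorted(set(issues), key=lambda i: (i.path, i.code)))
    return ValidationReport(issues=ordered)


def validate_din(meta: DINMetadata, level: int) -> ValidationReport:
    """Check DIN metadata against the cumulative element set of ``level``.

    Missing required elements are errors; when checking at level 1, absent
    level-2 elements yield an informational note (levels 1+2 are preferred
    but not required).
    """
    if level not in (1, 2, 3):
        raise InvalidLevelError(f"DIN level must be 1, 2 or 3, got {level!r}")
    present = set(meta.elements_map)
    issues: list[ValidationIssue] = []
    for element in terminology.din_required_elements(level):
        if element not in present:
            issues.append(
                _issue(
                    "DIN_LEVEL_UNMET",
                    f"din-metadata.{element}",
                    f"DIN element {element!r} required at level {level} is missing",
                )
            )
    if level == 1:
        for element in terminology.din_required_elements(2):
            if element not in present and element not in terminology.din_required_elements(1):
                issues.append(
                    _issue(
                        "DIN_LEVEL_PREFERRED",
                        f"din-metadata.{element}",
                        f"preferred level-2 DIN element {element!r} is absent",
                    )
                )
    return _finalize(issues)


def _entry_matches_rule(entry: Entry, rule_category: str, rule_code: str) -> bool:
    return entry.category == rule_category and entry.code[1] == rule_code


def validate_document(
    doc: NCDDocument,
    obligations: ObligationSet,
    din_level: int = 1,
    canonical_base: str = terminology.DEFAULT_CANONICAL_BASE,
) -> ValidationReport:
    """Validate one document against the guide's rule set.

    Rules, each reported at most once per offending element:

    1. the bundle's first entry is the composition;
    2. every composition reference resolves inside the bundle;
    3. every M / D-active element of ``obligations`` is present;
    4. game and lifestyle entry codes are members of their value sets;
    5. a practitioner link targets a record tagged with the NCD Practitioner
       profile;
    6. the DIN metadata satisfies ``din_level``;
    7. sections only reference entries of their own kind.
    """
    if din_level not in (1, 2, 3):
        raise InvalidLevelError(f"DIN level must be 1, 2 or 3, got {din_level!r}")
    if not isinstance(doc, NCDDocument):
        raise MalformedDocumentError(f"cannot traverse {type(doc).__name__} as a document")

    issues: list[ValidationIssue] = []
    header: CompositionHeader = doc.header

    # rule 1 — composition first
    if not doc.header_first:
        issues.append(
            _issue(
                "DOC_FIRST_ENTRY_NOT_COMPOSITION",
                "bundle.entry[0]",
                "first bundle entry is not the composition header",
            )
        )

    # rule 2 — reference closure
    ids = doc.resource_ids()
    for ref in doc.references():
        if ref not in ids:
            issues.append(
                _issue(
                    "UNRESOLVED_REFERENCE",
                    f"reference.{ref}",
                    f"composition references {ref!r} which is not in the bundle",
                )
            )

    # rule 3 — obligation satisfaction over the element table
    entries = doc.data_entries()
    rules_by_path = {rule.path: rule for rule in element_table()}
    for path in obligations.mandatory_paths():
        rule = rules_by_path.get(path)
        if rule is None or not rule.category:
            continue  # composition/section-level M elements are structural
        if not any(_entry_matches_rule(e, rule.category, rule.code) for e in entries):
            issues.append(
                _issue(
                    "MISSING_MANDATORY_ELEMENT",
                    path,
                    f"no entry for mandatory element {path!r}",
                )
            )

    # rule 4 — value-set membership for game/lifestyle codes
    systems = {
        "game": ("ncd-gamedata", terminology.canonical_uri("ncd-gamedata", canonical_base)),
        "lifestyle": ("ncd-lifestyle", terminology.canonical_uri("ncd-lifestyle", canonical_base)),
    }
    for entry in entries:
        if entry.category not in systems:
            continue
        system_id, system_uri = systems[entry.category]
        member_codes = {c.code for c in terminology.list_concepts(system_id)}
        if entry.code[0] != system_uri or entry.code[1] not in member_codes:
            issues.append(
                _issue(
                    "CODE_NOT_IN_VALUESET",
                    f"entry.{entry.entry_id}.code",
                    f"{entry.category} entry coded ({entry.code[0]!r}, {entry.code[1]!r}) "
                    f"is outside the {system_id!r} value set",
                )
            )

    # rule 5 — practitioner profile restriction
    if header.practitioner_ref is not None:
        target = next(
            (
                r
                for r in doc.entries
                if isinstance(r, PractitionerRecord) and r.resource_id == header.practitioner_ref
            ),
            None,
        )
        if target is not None and target.profile_tag != NCD_PRACTITIONER_PROFILE:
            issues.append(
                _issue(
                    "REFERENCE_PROFILE_VIOLATION",
                    f"composition.practitioner.{header.practitioner_ref}",
                    "practitioner link targets a record without the NCD Practitioner "
                    "profile tag",
                )
            )

    # rule 6 — DIN metadata level
    issues.extend(validate_din(header.din_metadata, din_level).issues)

    # rule 7 — section kind / entry category agreement
    by_id = {e.entry_id: e for e in entries}
    for section in header.sections:
        for ref in section.entry_refs:
            entry = by_id.get(ref)
            if entry is not None and entry.category != section.kind:
                issues.append(
                    _issue(
                        "SECTION_CATEGORY_MISMATCH",
                        f"section.{section.kind}.{ref}",
                        f"section {section.kind!r} references entry {ref!r} of "
                        f"category {entry.category!r}",
                    )
                )

    return _finalize(issues)


def explain_issue(code: str) -> str:
    """Catalogue description and severity for a known issue code."""
    try:
        severity, description = ISSUE_CATALOGUE[code]
    except KeyError:
        raise UnknownIssueCodeError(f"unknown issue code {code!r}") from None
    return f"[{severity}] {code}: {description}"
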