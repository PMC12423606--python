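"""Seeded synthetic sessions for the eight analyzed application archetypes.

The registry mirrors the comparative analysis the framework was derived from:
eight applications (G1 BreathIn … G8 DiaBeaThis) with their platform, type,
main NCD risk factor, and the data elements each produces.  The generator
emulates one export session of such an application — a pseudonymous patient,
a tagged practitioner, the three data sections, and ``n_entries`` coded
entries drawn from the archetype's produced elements — and is deterministic
per seed.  The fault injector perturbs a conformant document minimally so
that exactly one targeted validation rule breaks, for validator testing.

Numeric ranges are artifact choices (the underlying analysis prints none) and
are documented on their named constants.  Patients are pseudonymous only.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone
from functools import lru_cache
from importlib import resources
from typing import Optional

from . import terminology
from .errors import InvalidParamsError, UnknownArchetypeError, UnknownFaultError
from .model import (
    AppArchetype,
    DINMetadata,
    Entry,
    NCDDocument,
    Period,
    PatientRecord,
    PractitionerRecord,
    Quantity,
    Score,
    Text,
    add_entry,
    attach_practitioner,
    element_rule,
    element_table,
    entry_for_path,
    new_document,
    resolve_obligations,
)

# --- documented measurement ranges -----------------------------------------

#: Capillary blood glucose, mg/dL.  Spans hypo- to severe hyperglycemia so
#: synthetic diabetes sessions exercise the clinically interesting range.
GLUCOSE_RANGE_MG_DL = (40.0, 400.0)
#: Carbohydrates per meal entry, grams.
CARBOHYDRATE_RANGE_G = (0.0, 150.0)
#: Insulin per injection, international units.
INSULIN_RANGE_IU = (0.0, 30.0)
#: Physical activity per entry, minutes.
ACTIVITY_RANGE_MIN = (5, 180)
#: Ordinal mood scale (1 = very bad … 5 = very good); emoji pickers in the
#: analyzed apps map onto this five-point scale.
MOOD_SCALE = (1, 5)
#: Perceived-stress questionnaire total score (ten items, 0-4 each).
STRESS_SCORE_RANGE = (0, 40)
#: Energy per recorded meal, kilocalories.
NUTRITION_RANGE_KCAL = (50.0, 1500.0)
#: Cigarettes smoked per tracked day.
CIGARETTES_RANGE = (0, 40)
#: Alcohol units per entry.
ALCOHOL_RANGE_UNITS = (0.0, 10.0)
#: Game high scores, points.
HIGH_SCORE_RANGE = (0, 100_000)

_MOOD_EMOJI = {1: "😞", 2: "🙁", 3: "😐", 4: "🙂", 5: "😀"}

_ACHIEVEMENTS = (
    "first-session",
    "seven-day-streak",
    "level-up",
    "daily-goal-met",
    "perfect-week",
)
_NOTES = (
    "felt good today",
    "hard day, kept going",
    "tried a new recipe",
    "slept badly",
    "walked to work",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one synthetic session.

    ``n_entries`` must cover the archetype's dependent-mandatory elements
    (one entry each is emitted first, so the generated document always
    validates cleanly); the remainder is drawn uniformly from the
    archetype's produced elements.
    """

    seed: int
    n_entries: int = 10
    period: Optional[Period] = None

    def resolved_period(self) -> Period:
        if self.period is not None:
            return self.period
        return Period(
            start=datetime(2024, 1, 1, tzinfo=timezone.utc),
            end=datetime(2024, 1, 31, 23, 59, tzinfo=timezone.utc),
        )


@dataclass(frozen=True)
class FaultSpec:
    fault_kind: str
    expected_issue_code: str
    description: str


FAULT_CATALOGUE: tuple[FaultSpec, ...] = (
    FaultSpec(
        "header-displaced",
        "DOC_FIRST_ENTRY_NOT_COMPOSITION",
        "move the composition header out of first position",
    ),
    FaultSpec(
        "dangling-reference",
        "UNRESOLVED_REFERENCE",
        "add a section reference to a resource that is not in the bundle",
    ),
    FaultSpec(
        "missing-mandatory-element",
        "MISSING_MANDATORY_ELEMENT",
        "remove every entry of one dependent-mandatory element",
    ),
    FaultSpec(
        "out-of-valueset-code",
        "CODE_NOT_IN_VALUESET",
        "add a lifestyle entry whose code is outside the value set",
    ),
    FaultSpec(
        "untagged-practitioner",
        "REFERENCE_PROFILE_VIOLATION",
        "strip the NCD Practitioner profile tag from the linked practitioner",
    ),
    FaultSpec(
        "din-element-removed",
        "DIN_LEVEL_UNMET",
        "remove a core (level-1) DIN metadata element",
    ),
    FaultSpec(
        "section-category-mismatch",
        "SECTION_CATEGORY_MISMATCH",
        "move an entry reference into a section of another kind",
    ),
)


@dataclass(frozen=True)
class ArchetypeRegistry:
    archetypes: tuple[AppArchetype, ...]

    @property
    def archetypes_map(self) -> dict[str, AppArchetype]:
        return {a.archetype_id: a for a in self.archetypes}

    def __getitem__(self, archetype_id: str) -> AppArchetype:
        try:
            return self.archetypes_map[archetype_id]
        except KeyError:
            raise UnknownArchetypeError(f"unknown archetype id {archetype_id!r}") from None

    def ids(self) -> tuple[str, ...]:
        return tuple(a.archetype_id for a in self.archetypes)


@lru_cache(maxsize=None)
def archetype_registry() -> ArchetypeRegistry:
    """The packaged registry of the eight analyzed applications.

    Produced-element lists for the nutrition games (G2-G5) are best-effort
    reconstructions from narrative descriptions, flagged as such.
    """
    ref = resources.files("ncdkit.data").joinpath("archetypes.tsv")
    rows = []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                AppArchetype(
                    archetype_id=row["archetype_id"],
                    name=row["name"],
                    app_type=row["app_type"],
                    platform=row["platform"],
                    main_risk_factor=row["main_risk_factor"],
                    produced_elements=tuple(row["produced_elements"].split(";")),
                    best_effort=row["best_effort"] == "1",
                )
            )
    return ArchetypeRegistry(archetypes=tuple(rows))


def _sample_value(rng: random.Random, path: str):
    """Draw one plausible payload for an entry path. Returns (value, note)."""
    leaf = path.rsplit(".", 1)[1]
    if leaf == "blood-glucose":
        return Quantity(round(rng.uniform(*GLUCOSE_RANGE_MG_DL), 1), "mg/dL"), None
    if leaf == "carbohydrate-intake":
        return Quantity(round(rng.uniform(*CARBOHYDRATE_RANGE_G), 1), "g"), None
    if leaf == "insulin-dosage":
        return Quantity(round(rng.uniform(*INSULIN_RANGE_IU), 1), "IU"), None
    if leaf == "physical-activity":
        return Quantity(float(rng.randint(*ACTIVITY_RANGE_MIN)), "min"), rng.choice(
            ("walking", "cycling", "swimming", "strength training")
        )
    if leaf == "nutrition-intake":
        return Quantity(round(rng.uniform(*NUTRITION_RANGE_KCAL), 0), "kcal"), None
    if leaf == "stress-score":
        return Score(rng.randint(*STRESS_SCORE_RANGE)), None
    if leaf == "mood":
        level = rng.randint(*MOOD_SCALE)
        return Score(level), _MOOD_EMOJI[level]
    if leaf == "tobacco-use":
        return Quantity(float(rng.randint(*CIGARETTES_RANGE)), "cigarettes/day"), None
    if leaf == "alcohol-consumption":
        return Quantity(round(rng.uniform(*ALCOHOL_RANGE_UNITS), 1), "units"), None
    if leaf == "diary-entry":
        return Text(rng.choice(_NOTES)), None
    if leaf == "achievement":
        return Text(rng.choice(_ACHIEVEMENTS)), None
    if leaf == "high-score":
        return Score(rng.randint(*HIGH_SCORE_RANGE)), None
    if leaf == "other":
        return Score(rng.randint(0, 500)), "experience points"
    raise KeyError(f"no sampler for element path {path!r}")


def _din_for(archetype: AppArchetype) -> DINMetadata:
    """Level-2 DIN metadata describing the archetype (levels 1+2 preferred)."""
    elements = (
        ("title", archetype.name),
        ("publisher", "ncdkit synthetic session"),
        ("language", "en"),
        ("platform", archetype.platform),
        ("characterizing-goal", f"reduce {archetype.main_risk_factor} risk"),
        ("target-group", "adults"),
        ("genre", archetype.app_type),
        ("bct-list", "self-monitoring-of-behavior;feedback-on-behavior"),
        ("play-duration", "10min"),
    )
    return DINMetadata(declared_level=2, elements=elements)


def generate_session(archetype_id: str, params: GeneratorParams) -> NCDDocument:
    """Generate one conformant export-session document for an archetype.

    The document contains a pseudonymous patient, a practitioner tagged with
    the NCD Practitioner profile, level-2 DIN metadata, and ``n_entries``
    entries: first one per dependent-mandatory (D-active) element so the
    document always satisfies its own archetype's obligations, then uniform
    draws from the archetype's produced elements.  Identical parameters
    produce structurally identical documents.
    """
    registry = archetype_registry()
    if archetype_id not in registry.archetypes_map:
        raise UnknownArchetypeError(f"unknown archetype id {archetype_id!r}")
    archetype = registry[archetype_id]
    if params.n_entries < 1:
        raise InvalidParamsError("n_entries must be >= 1")
    period = params.resolved_period()

    obligations = resolve_obligations(archetype)
    active = [
        path
        for path, status in obligations.obligations
        if status == "D-active" and element_rule(path).category
    ]
    if params.n_entries < len(active):
        raise InvalidParamsError(
            f"{archetype_id} needs at least {len(active)} entries to cover its "
            f"dependent-mandatory elements, got {params.n_entries}"
        )

    rng = random.Random(params.seed)
    tag = archetype_id.lower()
    patient = PatientRecord(
        resource_id=f"patient-{tag}-{params.seed}",
        pseudonym=f"pseudonym-{rng.randint(10_000, 99_999)}",
        birth_year=rng.randint(1950, 2008),
    )
    doc = new_document(
        subject=patient,
        period=period,
        export_date=period.end,
        din=_din_for(archetype),
        document_id=f"{tag}-session-{params.seed}",
    )
    doc = attach_practitioner(
        doc,
        PractitionerRecord(
            resource_id=f"practitioner-{tag}-{params.seed}",
            pseudonym=f"practitioner-{rng.randint(1000, 9999)}",
        ),
    )

    paths = list(active)
    while len(paths) < params.n_entries:
        paths.append(rng.choice(archetype.produced_elements))

    span = (period.end - period.start) / max(params.n_entries, 1)
    for i, path in enumerate(paths):
        moment = period.start + i * span + timedelta(
            seconds=rng.uniform(0, max(span.total_seconds() - 1, 1))
        )
        moment = min(moment, period.end)
        value, note = _sample_value(rng, path)
        entry = entry_for_path(
            path,
            entry_id=f"{tag}-{params.seed}-e{i:03d}",
            effective_time=moment,
            value=value,
            note=note,
        )
        doc = add_entry(doc, entry)
    return doc


def inject_fault(
    doc: NCDDocument, fault: "FaultSpec | str", seed: int = 0
) -> tuple[NCDDocument, str]:
    """Minimally perturb a conformant document to break one targeted rule.

    Returns the perturbed document and the issue code validation must raise.
    The input document is never modified, so regenerating (or reusing) it
    restores conformance.
    """
    kind = fault if isinstance(fault, str) else fault.fault_kind
    spec = next((f for f in FAULT_CATALOGUE if f.fault_kind == kind), None)
    if spec is None:
        raise UnknownFaultError(f"unknown fault kind {kind!r}")
    rng = random.Random(seed)
    header = doc.header

    if kind == "header-displaced":
        rest = [r for r in doc.entries if r is not header]
        mutated = replace(doc, entries=(rest[0], header, *rest[1:]))

    elif kind == "dangling-reference":
        sections = tuple(
            replace(s, entry_refs=s.entry_refs + ("missing-resource",))
            if s.kind == "clinical"
            else s
            for s in header.sections
        )
        mutated = replace(doc, entries=(replace(header, sections=sections),) + doc.entries[1:])

    elif kind == "missing-mandatory-element":
        d_rules = [r for r in element_table() if r.obligation == "D" and r.category]
        victims = [
            e
            for e in doc.data_entries()
            for r in d_rules
            if e.category == r.category and e.code[1] == r.code
        ]
        if not victims:
            raise UnknownFaultError("document carries no dependent-mandatory entries")
        target = victims[0]
        drop = {
            e.entry_id
            for e in doc.data_entries()
            if e.category == target.category and e.code == target.code
        }
        sections = tuple(
            replace(s, entry_refs=tuple(r for r in s.entry_refs if r not in drop))
            for s in header.sections
        )
        entries = tuple(
            r
            for r in doc.entries[1:]
            if not (isinstance(r, Entry) and r.entry_id in drop)
        )
        mutated = replace(doc, entries=(replace(header, sections=sections),) + entries)

    elif kind == "out-of-valueset-code":
        rogue = Entry(
            entry_id=f"rogue-{rng.randint(100, 999)}",
            category="lifestyle",
            code=(terminology.canonical_uri("ncd-lifestyle"), "not-a-code"),
            effective_time=header.export_period.start,
            value=Text("rogue"),
        )
        mutated = add_entry(doc, rogue)

    elif kind == "untagged-practitioner":
        if header.practitioner_ref is None:
            raise UnknownFaultError("document has no practitioner link to untag")
        entries = tuple(
            replace(r, profile_tag="")
            if isinstance(r, PractitionerRecord) and r.resource_id == header.practitioner_ref
            else r
            for r in doc.entries
        )
        mutated = replace(doc, entries=entries)

    elif kind == "din-element-removed":
        core = terminology.din_required_elements(1)[0]
        din = header.din_metadata
        stripped = replace(
            din, elements=tuple((k, v) for k, v in din.elements if k != core)
        )
        mutated = replace(
            doc, entries=(replace(header, din_metadata=stripped),) + doc.entries[1:]
        )

    else:  # section-category-mismatch
        moved = None
        for s in header.sections:
            if s.entry_refs:
                moved = (s.kind, s.entry_refs[0])
                break
        if moved is None:
            raise UnknownFaultError("document has no entries to misplace")
        src_kind, ref = moved
        dst_kind = next(k for k in ("clinical", "game", "lifestyle") if k != src_kind)
        sections = []
        for s in header.sections:
            if s.kind == src_kind:
                sections.append(replace(s, entry_refs=tuple(r for r in s.entry_refs if r != ref)))
            elif s.kind == dst_kind:
                sections.append(replace(s, entry_refs=s.entry_refs + (ref,)))
            else:
                sections.append(s)
        mutated = replace(
            doc, entries=(replace(header, sections=tuple(sections)),) + doc.entries[1:]
        )

    return mutated, spec.expected_issue_code
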