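"""Controlled vocabularies for NCD-prevention game and application data.

The implementation guide modeled here ships two code systems with value sets:
``ncd-gamedata`` (types of game data: achievements, high scores, other) and
``ncd-lifestyle`` (types of lifestyle data: mood, alcohol consumption, tobacco
use, diary entry).  A third packaged vocabulary, ``ncd-bct``, names the
behavior change techniques the framework recommends; it supports the
compliance auditor and is not an implementation-guide code system.

All vocabularies and the DIN serious-game metadata scheme are loaded from
tabular text files under :mod:`ncdkit.data` (one concept per record: system,
code, display, definition) so they can be replaced without code changes.
External terminologies (SNOMED CT, LOINC) are bound by URI plus syntactic
code shape only; no terminology server is contacted.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

from .errors import InvalidLevelError, UnknownCodeError, UnknownSystemError

#: Default base for every canonical URI minted by this package.  The guide
#: modeled here publishes no canonical URLs, so local artifacts live under a
#: single configurable URN base.
DEFAULT_CANONICAL_BASE = "urn:ncdkit:"

#: Well-known URIs of the external terminologies the guide binds.
SNOMED_CT_URI = "http://snomed.info/sct"
LOINC_URI = "http://loinc.org"

#: LOINC codes are digits, a hyphen, and a single check digit (e.g. 2339-0).
_LOINC_SHAPE = re.compile(r"^\d{1,7}-\d$")
#: SNOMED CT identifiers are 6-18 digit integers.
_SNOMED_SHAPE = re.compile(r"^\d{6,18}$")
_KEBAB = re.compile(r"^[a-z0-9]+(-[a-z0-9]+)*$")


@dataclass(frozen=True)
class CodeConcept:
    """One coded concept inside a code system."""

    system_id: str
    code: str
    display: str
    definition: str = ""

    def __post_init__(self) -> None:
        if not _KEBAB.match(self.code):
            raise ValueError(f"concept code must be lowercase kebab-case: {self.code!r}")
        if not self.display:
            raise ValueError(f"concept {self.code!r} has an empty display")


@dataclass(frozen=True)
class CodeSystemDef:
    """A code system: identifier, canonical URI, title, ordered concepts."""

    system_id: str
    canonical_uri: str
    title: str
    concepts: tuple[CodeConcept, ...]
    is_ig_system: bool = True

    def __post_init__(self) -> None:
        if not self.concepts:
            raise ValueError(f"code system {self.system_id!r} has no concepts")
        codes = [c.code for c in self.concepts]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate codes in system {self.system_id!r}")


@dataclass(frozen=True)
class DINLevelScheme:
    """The three-level DIN descriptive-metadata scheme for serious games.

    Level 1 (core) is the minimum a conformant application supports; level 2
    adds supplementary descriptive elements (compliance with levels 1 and 2 is
    preferred); level 3 holds optional application profiles.  Element sets are
    cumulative: level k contains every level k-1 element.
    """

    levels: tuple[tuple[str, ...], ...]  # levels[k-1] = cumulative elements of level k

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("DIN scheme must define exactly 3 levels")
        if not self.levels[0]:
            raise ValueError("DIN level 1 (core) must be non-empty")
        for k in (1, 2):
            if not set(self.levels[k - 1]) <= set(self.levels[k]):
                raise ValueError(f"DIN level {k} is not a subset of level {k + 1}")

    def required_elements(self, level: int) -> tuple[str, ...]:
        if level not in (1, 2, 3):
            raise InvalidLevelError(f"DIN level must be 1, 2 or 3, got {level!r}")
        return self.levels[level - 1]


@dataclass(frozen=True)
class BindingSlot:
    """A value-set binding slot on an element.

    ``terminology`` selects the admissibility rule: ``local`` checks
    membership in a packaged code system; ``snomed-ct`` and ``loinc`` check
    the well-known system URI plus the syntactic code shape (the toolkit
    distributes no external terminology content).
    """

    slot_id: str
    terminology: str  # "snomed-ct" | "loinc" | "local"
    allowed_codes: Optional[tuple[str, ...]] = None
    local_system_id: Optional[str] = None
    canonical_base: str = DEFAULT_CANONICAL_BASE

    def __post_init__(self) -> None:
        if self.terminology not in ("snomed-ct", "loinc", "local"):
            raise ValueError(f"unknown terminology {self.terminology!r}")
        if self.terminology == "local" and self.local_system_id is None:
            raise ValueError("local binding slots must name a packaged code system")


def canonical_uri(system_id: str, base: str = DEFAULT_CANONICAL_BASE) -> str:
    """Canonical URI of a local code system under a configurable base."""
    return f"{base}CodeSystem/{system_id}"


def _read_tsv(name: str) -> list[dict[str, str]]:
    ref = resources.files("ncdkit.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return [
            {k: (v or "") for k, v in row.items()}
            for row in csv.DictReader(fh, delimiter="\t")
        ]


@lru_cache(maxsize=None)
def _registry() -> dict[str, CodeSystemDef]:
    meta = {row["system_id"]: row for row in _read_tsv("systems.tsv")}
    by_system: dict[str, list[CodeConcept]] = {sid: [] for sid in meta}
    for row in _read_tsv("concepts.tsv"):
        by_system[row["system_id"]].append(
            CodeConcept(row["system_id"], row["code"], row["display"], row["definition"])
        )
    registry = {
        sid: CodeSystemDef(
            system_id=sid,
            canonical_uri=canonical_uri(sid),
            title=meta[sid]["title"],
            concepts=tuple(concepts),
            is_ig_system=meta[sid]["ig"] == "1",
        )
        for sid, concepts in by_system.items()
    }
    uris = [s.canonical_uri for s in registry.values()]
    if len(set(uris)) != len(uris):
        raise ValueError("canonical URIs are not unique across packaged systems")
    return registry


def packaged_systems() -> tuple[CodeSystemDef, ...]:
    """All packaged code systems, IG systems first, in declaration order."""
    return tuple(_registry().values())


def get_system(system_id: str) -> CodeSystemDef:
    try:
        return _registry()[system_id]
    except KeyError:
        raise UnknownSystemError(f"unknown code system {system_id!r}") from None


def list_concepts(system_id: str) -> tuple[CodeConcept, ...]:
    """Concepts of a packaged system, in declaration order (immutable)."""
    return get_system(system_id).concepts


def lookup_code(system_id: str, code: str) -> CodeConcept:
    """Case-sensitive lookup of one concept within a packaged system."""
    for concept in list_concepts(system_id):
        if concept.code == code:
            return concept
    raise UnknownCodeError(f"code {code!r} not in system {system_id!r}")


def validate_binding(slot: BindingSlot, system_uri: str, code: str) -> bool:
    """True iff ``(system_uri, code)`` is admissible for the slot.

    Never raises: any mismatch — wrong URI, empty or malformed code, code
    outside the bound value set — yields ``False``.
    """
    if not code:
        return False
    if slot.terminology == "loinc":
        ok = system_uri == LOINC_URI and bool(_LOINC_SHAPE.match(code))
    elif slot.terminology == "snomed-ct":
        ok = system_uri == SNOMED_CT_URI and bool(_SNOMED_SHAPE.match(code))
    else:
        assert slot.local_system_id is not None
        try:
            system = get_system(slot.local_system_id)
        except UnknownSystemError:
            return False
        expected = canonical_uri(slot.local_system_id, slot.canonical_base)
        ok = system_uri == expected and any(c.code == code for c in system.concepts)
    if ok and slot.allowed_codes is not None:
        ok = code in slot.allowed_codes
    return ok


@lru_cache(maxsize=None)
def din_scheme() -> DINLevelScheme:
    """The packaged DIN metadata scheme (replaceable data file)."""
    per_level: dict[int, list[str]] = {1: [], 2: [], 3: []}
    for row in _read_tsv("din_scheme.tsv"):
        per_level[int(row["level"])].append(row["element"])
    level1 = tuple(per_level[1])
    level2 = level1 + tuple(per_level[2])
    level3 = level2 + tuple(per_level[3])
    return DINLevelScheme(levels=(level1, level2, level3))


def din_required_elements(level: int) -> tuple[str, ...]:
    """Cumulative DIN metadata elements required at ``level`` (1-3)."""
    return din_scheme().required_elements(level)
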