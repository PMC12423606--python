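"""Reading and writing NCD documents as FHIR R5-style JSON document bundles.

The on-disk shape is a bundle of type ``document`` whose first entry is the
composition; the composition carries the three guide extensions (export
period, export date, DIN metadata) and one section per data category, and
references every other resource in the bundle by full URL.  Entries are
emitted as Observation-shaped resources, actors as Patient / Practitioner /
RelatedPerson-shaped resources with their profile tags in ``meta.profile``.

Canonical URIs for local profiles, code systems, and extensions live under a
configurable base.  Output is deterministic: equal documents and configs
produce byte-identical text.  Unknown fields found on read are preserved in
an opaque side-channel and re-emitted on write, so read-then-write is
lossless for conformant foreign documents.  XML is deliberately unsupported.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import datetime
from typing import Any, Optional

from . import terminology
from .errors import MalformedDocumentError, ParseError, SerializationError
from .model import (
    CompositionHeader,
    DINMetadata,
    Entry,
    NCDDocument,
    PatientRecord,
    Period,
    PractitionerRecord,
    Quantity,
    RelatedPersonRecord,
    Score,
    SectionComposition,
    Coded,
    Text,
)

_SEMVER = re.compile(r"^\d+\.\d+\.\d+$")
_ABS_URI = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:")


@dataclass(frozen=True)
class SerializationConfig:
    canonical_base: str = terminology.DEFAULT_CANONICAL_BASE
    pretty: bool = False
    fhir_version_label: str = "5.0.0"
    din_as_text: bool = True

    def __post_init__(self) -> None:
        if not _ABS_URI.match(self.canonical_base):
            raise ValueError(f"canonical_base must be an absolute URI: {self.canonical_base!r}")
        if not _SEMVER.match(self.fhir_version_label):
            raise ValueError(f"fhir_version_label must look like a semver: {self.fhir_version_label!r}")

    def structure_definition(self, tag: str) -> str:
        return f"{self.canonical_base}StructureDefinition/{tag}"

    def extension_url(self, name: str) -> str:
        return f"{self.canonical_base}Extension/{name}"

    def full_url(self, resource_id: str) -> str:
        return f"{self.canonical_base}Resource/{resource_id}"


DEFAULT_CONFIG = SerializationConfig()

_KNOWN_BUNDLE_KEYS = {"resourceType", "id", "meta", "type", "entry"}
_KNOWN_RESOURCE_KEYS = {
    "Composition": {
        "resourceType", "id", "status", "type", "date", "title", "subject",
        "extension", "section",
    },
    "Observation": {
        "resourceType", "id", "status", "category", "code", "effectiveDateTime",
        "effectivePeriod", "valueQuantity", "valueInteger", "valueString",
        "valueCodeableConcept", "note",
    },
    "Patient": {"resourceType", "id", "meta", "name", "birthDate"},
    "Practitioner": {"resourceType", "id", "meta", "name"},
    "RelatedPerson": {"resourceType", "id", "meta", "name", "relationship"},
}


# ---------------------------------------------------------------------------
# writing


def _dt(value: datetime) -> str:
    return value.isoformat()


def _period_json(period: Period) -> dict[str, str]:
    return {"start": _dt(period.start), "end": _dt(period.end)}


def _din_extension(din: DINMetadata, cfg: SerializationConfig) -> dict[str, Any]:
    url = cfg.extension_url("din-metadata")
    if cfg.din_as_text:
        # the exchange shape: one free-text field carrying the DIN metadata
        return {"url": url, "valueString": din.render_text()}
    nested: list[dict[str, Any]] = [
        {"url": "declared-level", "valueInteger": din.declared_level}
    ]
    nested.extend({"url": k, "valueString": v} for k, v in din.elements)
    return {"url": url, "extension": nested}


def _composition_json(doc: NCDDocument, cfg: SerializationConfig) -> dict[str, Any]:
    hdr = doc.header
    extensions: list[dict[str, Any]] = [
        {
            "url": cfg.extension_url("export-period"),
            "valuePeriod": _period_json(hdr.export_period),
        },
        {"url": cfg.extension_url("export-date"), "valueDateTime": _dt(hdr.export_date)},
        _din_extension(hdr.din_metadata, cfg),
    ]
    if hdr.practitioner_ref is not None:
        extensions.append(
            {
                "url": cfg.extension_url("practitioner-link"),
                "valueReference": {"reference": cfg.full_url(hdr.practitioner_ref)},
            }
        )
    for ref in hdr.related_person_refs:
        extensions.append(
            {
                "url": cfg.extension_url("related-person-link"),
                "valueReference": {"reference": cfg.full_url(ref)},
            }
        )
    sections = [
        {
            "title": f"{sec.kind} data",
            "code": {
                "coding": [
                    {
                        "system": f"{cfg.canonical_base}CodeSystem/ncd-sections",
                        "code": sec.kind,
                    }
                ]
            },
            "entry": [{"reference": cfg.full_url(r)} for r in sec.entry_refs],
        }
        for sec in hdr.sections
    ]
    return {
        "resourceType": "Composition",
        "id": f"{doc.document_id}-composition",
        "status": "final",
        "type": {"text": "NCD prevention game and application data export"},
        "date": _dt(hdr.export_date),
        "title": "NCD document",
        "subject": {"reference": cfg.full_url(hdr.subject_ref)},
        "extension": extensions,
        "section": sections,
    }


def _entry_json(entry: Entry, cfg: SerializationConfig) -> dict[str, Any]:
    out: dict[str, Any] = {
        "resourceType": "Observation",
        "id": entry.entry_id,
        "status": "final",
        "category": [
            {
                "coding": [
                    {
                        "system": f"{cfg.canonical_base}CodeSystem/ncd-sections",
                        "code": entry.category,
                    }
                ]
            }
        ],
        "code": {"coding": [{"system": entry.code[0], "code": entry.code[1]}]},
    }
    if isinstance(entry.effective_time, Period):
        out["effectivePeriod"] = _period_json(entry.effective_time)
    else:
        out["effectiveDateTime"] = _dt(entry.effective_time)
    value = entry.value
    if isinstance(value, Quantity):
        out["valueQuantity"] = {"value": value.value, "unit": value.unit}
    elif isinstance(value, Score):
        out["valueInteger"] = value.value
    elif isinstance(value, Text):
        out["valueString"] = value.value
    else:
        out["valueCodeableConcept"] = {"coding": [{"code": value.token}]}
    if entry.note is not None:
        out["note"] = [{"text": entry.note}]
    return out


def _actor_json(res: Any, cfg: SerializationConfig) -> dict[str, Any]:
    if isinstance(res, PatientRecord):
        out: dict[str, Any] = {"resourceType": "Patient", "id": res.resource_id}
        if res.profile_tag:
            out["meta"] = {"profile": [cfg.structure_definition(res.profile_tag)]}
        out["name"] = [{"text": res.pseudonym}]
        if res.birth_year is not None:
            out["birthDate"] = str(res.birth_year)
        return out
    if isinstance(res, PractitionerRecord):
        out = {"resourceType": "Practitioner", "id": res.resource_id}
        if res.profile_tag:
            out["meta"] = {"profile": [cfg.structure_definition(res.profile_tag)]}
        out["name"] = [{"text": res.pseudonym}]
        return out
    assert isinstance(res, RelatedPersonRecord)
    out = {"resourceType": "RelatedPerson", "id": res.resource_id}
    if res.profile_tag:
        out["meta"] = {"profile": [cfg.structure_definition(res.profile_tag)]}
    out["name"] = [{"text": res.pseudonym}]
    out["relationship"] = [{"text": res.relationship}]
    return out


def write_document(doc: NCDDocument, cfg: SerializationConfig = DEFAULT_CONFIG) -> str:
    """Serialize a document to FHIR-style JSON text.

    The document must satisfy the model invariants (header first, reference
    closure); anything else raises :class:`SerializationError`.
    """
    if not doc.header_first:
        raise SerializationError("cannot serialize: composition header is not first")
    if not doc.is_closed():
        raise SerializationError("cannot serialize: unresolved composition references")

    extras = dict(doc.extras)
    entries: list[dict[str, Any]] = []
    for res in doc.entries:
        if isinstance(res, CompositionHeader):
            resource = _composition_json(doc, cfg)
        elif isinstance(res, Entry):
            resource = _entry_json(res, cfg)
        else:
            resource = _actor_json(res, cfg)
        rid = resource["id"]
        for key, raw in extras.items():
            prefix = f"resource.{rid}."
            if key.startswith(prefix):
                resource[key[len(prefix):]] = json.loads(raw)
        entries.append({"fullUrl": cfg.full_url(rid), "resource": resource})

    bundle: dict[str, Any] = {
        "resourceType": "Bundle",
        "id": doc.document_id,
        "meta": {
            "profile": [cfg.structure_definition(doc.profile_tag)],
            "tag": [
                {
                    "system": f"{cfg.canonical_base}fhir-version",
                    "code": cfg.fhir_version_label,
                }
            ],
        },
        "type": "document",
        "entry": entries,
    }
    for key, raw in extras.items():
        if key.startswith("bundle."):
            bundle[key[len("bundle."):]] = json.loads(raw)
    if cfg.pretty:
        return json.dumps(bundle, indent=2, ensure_ascii=False) + "\n"
    return json.dumps(bundle, separators=(",", ":"), ensure_ascii=False)


# ---------------------------------------------------------------------------
# reading


def _ref_id(reference: dict[str, Any], cfg: SerializationConfig) -> str:
    ref = reference.get("reference", "")
    prefix = f"{cfg.canonical_base}Resource/"
    return ref[len(prefix):] if ref.startswith(prefix) else ref


def _parse_dt(text: str) -> datetime:
    return datetime.fromisoformat(text)


def _parse_period(obj: dict[str, Any]) -> Period:
    return Period(start=_parse_dt(obj["start"]), end=_parse_dt(obj["end"]))


def _profile_tag(resource: dict[str, Any], cfg: SerializationConfig) -> str:
    profiles = resource.get("meta", {}).get("profile", [])
    if not profiles:
        return ""
    prefix = f"{cfg.canonical_base}StructureDefinition/"
    first = profiles[0]
    return first[len(prefix):] if first.startswith(prefix) else first


def _parse_composition(
    resource: dict[str, Any], cfg: SerializationConfig
) -> CompositionHeader:
    period: Optional[Period] = None
    export_date: Optional[datetime] = None
    din: Optional[DINMetadata] = None
    practitioner: Optional[str] = None
    related: list[str] = []
    for ext in resource.get("extension", []):
        url = ext.get("url", "")
        name = url.rsplit("/", 1)[-1]
        if name == "export-period":
            period = _parse_period(ext["valuePeriod"])
        elif name == "export-date":
            export_date = _parse_dt(ext["valueDateTime"])
        elif name == "din-metadata":
            if "valueString" in ext:
                din = DINMetadata.from_text(ext["valueString"])
            else:
                level, pairs = 1, []
                for sub in ext.get("extension", []):
                    if sub["url"] == "declared-level":
                        level = sub["valueInteger"]
                    else:
                        pairs.append((sub["url"], sub["valueString"]))
                din = DINMetadata(declared_level=level, elements=tuple(pairs))
        elif name == "practitioner-link":
            practitioner = _ref_id(ext["valueReference"], cfg)
        elif name == "related-person-link":
            related.append(_ref_id(ext["valueReference"], cfg))
    if period is None or export_date is None or din is None:
        raise MalformedDocumentError(
            "composition lacks one of its three extensions "
            "(export-period, export-date, din-metadata)"
        )
    sections = []
    for sec in resource.get("section", []):
        kind = sec.get("code", {}).get("coding", [{}])[0].get("code", "")
        refs = tuple(_ref_id(r, cfg) for r in sec.get("entry", []))
        sections.append(SectionComposition(kind=kind, entry_refs=refs))
    subject = resource.get("subject")
    if subject is None:
        raise MalformedDocumentError("composition lacks a subject reference")
    return CompositionHeader(
        export_period=period,
        export_date=export_date,
        din_metadata=din,
        subject_ref=_ref_id(subject, cfg),
        sections=tuple(sections),
        practitioner_ref=practitioner,
        related_person_refs=tuple(related),
    )


def _parse_observation(resource: dict[str, Any]) -> Entry:
    category = (
        resource.get("category", [{}])[0].get("coding", [{}])[0].get("code", "")
    )
    coding = resource.get("code", {}).get("coding", [{}])[0]
    if "effectivePeriod" in resource:
        effective: Any = _parse_period(resource["effectivePeriod"])
    else:
        effective = _parse_dt(resource["effectiveDateTime"])
    value: Any
    if "valueQuantity" in resource:
        q = resource["valueQuantity"]
        value = Quantity(q["value"], q["unit"])
    elif "valueInteger" in resource:
        value = Score(resource["valueInteger"])
    elif "valueString" in resource:
        value = Text(resource["valueString"])
    elif "valueCodeableConcept" in resource:
        value = Coded(resource["valueCodeableConcept"]["coding"][0]["code"])
    else:
        raise MalformedDocumentError(f"observation {resource.get('id')!r} has no value")
    notes = resource.get("note", [])
    return Entry(
        entry_id=resource["id"],
        category=category,
        code=(coding.get("system", ""), coding.get("code", "")),
        effective_time=effective,
        value=value,
        note=notes[0]["text"] if notes else None,
    )


def read_document(text: str, cfg: SerializationConfig = DEFAULT_CONFIG) -> NCDDocument:
    """Parse FHIR-style JSON text back into a document.

    Raises :class:`ParseError` for non-JSON input and
    :class:`MalformedDocumentError` for JSON that is not a document bundle.
    Unknown fields are preserved in the document's opaque side-channel so a
    subsequent write loses nothing.
    """
    try:
        bundle = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"input is not well-formed JSON: {exc}") from None
    if not isinstance(bundle, dict) or bundle.get("resourceType") != "Bundle":
        raise MalformedDocumentError("input JSON is not a FHIR Bundle")
    if bundle.get("type") != "document":
        raise MalformedDocumentError("bundle is not of type 'document'")
    if not isinstance(bundle.get("entry"), list) or not bundle["entry"]:
        raise MalformedDocumentError("document bundle has no entries")

    extras: list[tuple[str, str]] = []
    for key, value in bundle.items():
        if key not in _KNOWN_BUNDLE_KEYS:
            extras.append((f"bundle.{key}", json.dumps(value)))

    resources_out: list[Any] = []
    for item in bundle["entry"]:
        resource = item.get("resource")
        if not isinstance(resource, dict) or "resourceType" not in resource:
            raise MalformedDocumentError("bundle entry without a resource")
        rtype = resource["resourceType"]
        if rtype == "Composition":
            resources_out.append(_parse_composition(resource, cfg))
        elif rtype == "Observation":
            resources_out.append(_parse_observation(resource))
        elif rtype == "Patient":
            birth = resource.get("birthDate")
            resources_out.append(
                PatientRecord(
                    resource_id=resource["id"],
                    pseudonym=resource.get("name", [{}])[0].get("text", ""),
                    birth_year=int(birth) if birth else None,
                    profile_tag=_profile_tag(resource, cfg),
                )
            )
        elif rtype == "Practitioner":
            resources_out.append(
                PractitionerRecord(
                    resource_id=resource["id"],
                    pseudonym=resource.get("name", [{}])[0].get("text", ""),
                    profile_tag=_profile_tag(resource, cfg),
                )
            )
        elif rtype == "RelatedPerson":
            resources_out.append(
                RelatedPersonRecord(
                    resource_id=resource["id"],
                    pseudonym=resource.get("name", [{}])[0].get("text", ""),
                    relationship=resource.get("relationship", [{}])[0].get("text", "related"),
                    profile_tag=_profile_tag(resource, cfg),
                )
            )
        else:
            raise MalformedDocumentError(f"unsupported resource type {rtype!r}")
        for key, value in resource.items():
            if key not in _KNOWN_RESOURCE_KEYS[rtype]:
                extras.append((f"resource.{resource['id']}.{key}", json.dumps(value)))

    if not any(isinstance(r, CompositionHeader) for r in resources_out):
        raise MalformedDocumentError("document bundle contains no composition")

    profile_tag = _profile_tag({"meta": bundle.get("meta", {})}, cfg) or "ncd-bundle"
    return NCDDocument(
        document_id=bundle.get("id", "document"),
        entries=tuple(resources_out),
        profile_tag=profile_tag,
        extras=tuple(extras),
    )
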