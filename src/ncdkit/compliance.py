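"""Requirement auditing with RFC 2119 semantics and the key-area matrix.

The framework's requirement catalog holds 14 requirements (R01-R14), each at
one of the RFC 2119 levels — *must* (an absolute requirement), *should*
(recommended, with valid reasons to deviate), *may* (truly optional) — and
typed functional or nonfunctional.  An application manifest describes a game
or app's capabilities; the auditor scores every requirement from the
manifest, derives a verdict (any unfulfilled must ⇒ noncompliant; otherwise
any not-fully-met should ⇒ conditionally-compliant; otherwise compliant),
checks coverage of the recommended behavior change techniques, and
aggregates per-app key-area fulfillment (C1 organizational … C6 technical)
into a matrix.

Key areas C1 and C3-C6 are not machine-checkable from a manifest; their cells
come from declared evidence.  Only C2 (design and development best practices)
is recomputed from the requirement audit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import terminology
from .errors import CatalogCorruptError, InvalidManifestError

LEVELS = ("must", "should", "may")
REQ_TYPES = ("functional", "nonfunctional")
KEY_AREAS = ("C1", "C2", "C3", "C4", "C5", "C6")
STATUSES = ("fulfilled", "partial", "unfulfilled")
FULFILLMENTS = ("none", "partial", "full")
VERDICTS = ("compliant", "conditionally-compliant", "noncompliant")

#: BCTs every new application should implement.
CORE_BCTS = (
    "information-about-health-consequences",
    "self-monitoring-of-behavior",
    "feedback-on-behavior",
)
#: BCTs recommended conditionally (game- and target-group-dependent).
CONDITIONAL_BCTS = ("incentive-outcome", "social-support", "social-comparison")

#: Genres the best practices single out as well suited to mobile play.
RECOMMENDED_GENRES = ("platformer", "adventure")


@dataclass(frozen=True)
class RequirementItem:
    req_id: str
    description: str
    level: str
    req_type: str
    key_area: str


@lru_cache(maxsize=None)
def load_requirement_catalog() -> tuple[RequirementItem, ...]:
    """The packaged 14-item requirement catalog, in R01..R14 order."""
    ref = resources.files("ncdkit.data").joinpath("requirements.tsv")
    items = []
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            items.append(
                RequirementItem(
                    req_id=row["req_id"],
                    description=row["description"],
                    level=row["level"],
                    req_type=row["req_type"],
                    key_area=row["key_area"],
                )
            )
    ids = [i.req_id for i in items]
    if len(items) != 14 or len(set(ids)) != 14 or ids != sorted(ids):
        raise CatalogCorruptError("requirement catalog must hold R01..R14 exactly once")
    for item in items:
        if item.level not in LEVELS or item.req_type not in REQ_TYPES or item.key_area not in KEY_AREAS:
            raise CatalogCorruptError(f"requirement {item.req_id} has out-of-set fields")
    return tuple(items)


class AppManifest(BaseModel):
    """Structured description of one application for auditing."""

    app_id: str
    app_name: str
    app_type: str
    platform: str
    risk_factor: str
    bct_list: tuple[str, ...] = ()
    gamification_elements: tuple[str, ...] = ()
    educational_content: bool = False
    usability_tested: bool = False
    graphics: bool = False
    audio: bool = False
    genre: str = ""
    intuitive_controls: bool = False
    social_features: tuple[str, ...] = ()
    availability: bool = False
    cost: Literal["free", "low", "paid"] = "free"
    platform_barrier: Literal["low", "high"] = "low"
    clinician_involved: bool = False
    interoperable_export: bool = False
    key_area_evidence: dict[str, Literal["none", "partial", "full"]] = Field(
        default_factory=dict
    )

    @field_validator("bct_list")
    @classmethod
    def _bcts_resolvable(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        known = {c.code for c in terminology.list_concepts("ncd-bct")}
        unknown = [code for code in v if code not in known]
        if unknown:
            raise ValueError(f"unknown BCT codes {unknown!r} (not in 'ncd-bct')")
        return v

    @field_validator("key_area_evidence")
    @classmethod
    def _evidence_total(cls, v: dict[str, str]) -> dict[str, str]:
        if set(v) != set(KEY_AREAS):
            raise ValueError(f"key_area_evidence must cover exactly {KEY_AREAS}")
        return v


def load_manifest(text: str) -> AppManifest:
    """Parse one YAML manifest; invalid content raises INVALID_MANIFEST."""
    try:
        data = yaml.safe_load(text)
        return AppManifest.model_validate(data)
    except Exception as exc:
        raise InvalidManifestError(str(exc)) from exc


@lru_cache(maxsize=None)
def packaged_manifests() -> tuple[AppManifest, ...]:
    """Fixture manifests encoding the eight analyzed applications."""
    base = resources.files("ncdkit.data").joinpath("manifests")
    out = []
    for i in range(1, 9):
        text = base.joinpath(f"g{i}.yaml").read_text(encoding="utf-8")
        out.append(load_manifest(text))
    return tuple(out)


@dataclass(frozen=True)
class AuditReport:
    app_id: str
    per_requirement: tuple[tuple[str, str], ...]  # (req_id, status) in catalog order
    verdict: str
    notes: tuple[str, ...] = ()

    def status(self, req_id: str) -> str:
        return dict(self.per_requirement)[req_id]

    def to_text(self) -> str:
        lines = [f"audit: {self.app_id}", f"verdict: {self.verdict}"]
        catalog = {i.req_id: i for i in load_requirement_catalog()}
        for req_id, status in self.per_requirement:
            item = catalog[req_id]
            lines.append(f"{req_id}\t{item.level}\t{status}\t{item.description}")
        lines.extend(f"note: {n}" for n in self.notes)
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        catalog = {i.req_id: i for i in load_requirement_catalog()}
        return pd.DataFrame(
            [
                {
                    "req_id": rid,
                    "level": catalog[rid].level,
                    "req_type": catalog[rid].req_type,
                    "status": status,
                }
                for rid, status in self.per_requirement
            ]
        )


def _score_requirement(item: RequirementItem, m: AppManifest) -> str:
    """Documented manifest-field → requirement mapping (editorial rule)."""
    if item.req_id == "R01":
        return "fulfilled" if m.bct_list else "unfulfilled"
    if item.req_id == "R02":
        return "fulfilled" if m.gamification_elements else "unfulfilled"
    if item.req_id == "R03":
        return "fulfilled" if m.educational_content else "unfulfilled"
    if item.req_id == "R04":
        return "fulfilled" if m.usability_tested else "unfulfilled"
    if item.req_id == "R05":
        return "fulfilled" if m.graphics else "unfulfilled"
    if item.req_id == "R06":
        return "fulfilled" if m.audio else "unfulfilled"
    if item.req_id == "R07":
        if m.genre in RECOMMENDED_GENRES:
            return "fulfilled"
        return "partial" if m.genre else "unfulfilled"
    if item.req_id == "R08":
        return "fulfilled" if m.intuitive_controls else "unfulfilled"
    if item.req_id == "R09":
        return "fulfilled" if m.social_features else "unfulfilled"
    if item.req_id == "R10":
        return "fulfilled" if m.availability else "unfulfilled"
    if item.req_id == "R11":
        return "fulfilled" if m.cost in ("free", "low") else "unfulfilled"
    if item.req_id == "R12":
        return "fulfilled" if m.platform_barrier == "low" else "unfulfilled"
    if item.req_id == "R13":
        return "fulfilled" if m.clinician_involved else "unfulfilled"
    assert item.req_id == "R14"
    return "fulfilled" if m.interoperable_export else "unfulfilled"


def rfc2119_verdict(
    per_requirement: dict[str, str] | tuple[tuple[str, str], ...],
    catalog: Optional[Iterable[RequirementItem]] = None,
) -> str:
    """Derive the compliance verdict from per-requirement statuses.

    Any unfulfilled *must* ⇒ noncompliant.  Otherwise any *should* that is
    not fully met (partial counts) ⇒ conditionally-compliant.  Otherwise
    compliant — *may* items never worsen the verdict.  A partially met
    *must* is still short of an absolute requirement ⇒ noncompliant.
    """
    statuses = dict(per_requirement)
    items = tuple(catalog) if catalog is not None else load_requirement_catalog()
    if set(statuses) != {i.req_id for i in items}:
        raise ValueError("per_requirement must be total over the catalog ids")
    if any(statuses[i.req_id] != "fulfilled" for i in items if i.level == "must"):
        return "noncompliant"
    if any(statuses[i.req_id] != "fulfilled" for i in items if i.level == "should"):
        return "conditionally-compliant"
    return "compliant"


def audit_manifest(manifest: AppManifest) -> AuditReport:
    """Score all 14 requirements for one manifest and derive the verdict."""
    catalog = load_requirement_catalog()
    per_req = tuple((item.req_id, _score_requirement(item, manifest)) for item in catalog)
    statuses = dict(per_req)
    notes = tuple(
        f"{item.req_id} ({item.level}) not fulfilled: {item.description}"
        for item in catalog
        if statuses[item.req_id] != "fulfilled"
    )
    return AuditReport(
        app_id=manifest.app_id,
        per_requirement=per_req,
        verdict=rfc2119_verdict(per_req, catalog),
        notes=notes,
    )


def bct_coverage(manifest: AppManifest) -> tuple[tuple[str, bool], ...]:
    """Presence of each recommended (core + conditional) BCT in the manifest."""
    present = set(manifest.bct_list)
    return tuple((code, code in present) for code in CORE_BCTS + CONDITIONAL_BCTS)


@dataclass(frozen=True)
class KeyAreaMatrix:
    """Per-app key-area fulfillment (rows: apps, columns: C1-C6)."""

    rows: tuple[tuple[str, tuple[str, ...]], ...]  # (app_id, 6 cells)

    def cell(self, app_id: str, key_area: str) -> str:
        cells = dict(self.rows)[app_id]
        return cells[KEY_AREAS.index(key_area)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(zip(KEY_AREAS, cells), app=app_id) for app_id, cells in self.rows]
        ).set_index("app") if self.rows else pd.DataFrame(columns=KEY_AREAS)

    def to_csv(self) -> str:
        frame = self.to_frame()
        return frame.to_csv(index=True if len(frame) else False)


def _c2_from_audit(report: AuditReport) -> str:
    c2_ids = [i.req_id for i in load_requirement_catalog() if i.key_area == "C2"]
    statuses = [report.status(rid) for rid in c2_ids]
    if all(s == "fulfilled" for s in statuses):
        return "full"
    if any(s in ("fulfilled", "partial") for s in statuses):
        return "partial"
    return "none"


def key_area_matrix(manifests: Iterable[AppManifest]) -> KeyAreaMatrix:
    """Aggregate key-area fulfillment over manifests, sorted by app id.

    Cells are copied from each manifest's declared evidence except C2, which
    is recomputed from the requirement audit.
    """
    rows = []
    for manifest in sorted(manifests, key=lambda m: m.app_id):
        evidence = dict(manifest.key_area_evidence)
        evidence["C2"] = _c2_from_audit(audit_manifest(manifest))
        rows.append((manifest.app_id, tuple(evidence[k] for k in KEY_AREAS)))
    return KeyAreaMatrix(rows=tuple(rows))
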