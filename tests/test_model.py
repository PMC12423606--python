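"""Document construction, purity, closure, and obligation resolution."""

from datetime import datetime, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncdkit import terminology
from ncdkit.errors import (
    CodeCategoryMismatchError,
    DuplicatePractitionerError,
    InvalidPeriodError,
    UnknownArchetypeError,
)
from ncdkit.model import (
    DINMetadata,
    PatientRecord,
    Period,
    PractitionerRecord,
    Quantity,
    RelatedPersonRecord,
    Score,
    Text,
    add_entry,
    attach_practitioner,
    attach_related_person,
    element_table,
    entry_for_path,
    new_document,
    resolve_obligations,
)
from ncdkit.synth import archetype_registry

UTC = timezone.utc


def ts(day, hour=12):
    return datetime(2024, 1, day, hour, tzinfo=UTC)


class TestNewDocument:
    def test_minimal_document_shape(self, minimal_doc):
        assert len(minimal_doc.entries) == 2  # header + patient
        hdr = minimal_doc.header
        assert sorted(s.kind for s in hdr.sections) == ["clinical", "game", "lifestyle"]
        assert all(not s.entry_refs for s in hdr.sections)
        assert minimal_doc.is_closed()

    def test_inverted_period_rejected(self):
        with pytest.raises(InvalidPeriodError):
            Period(start=ts(31), end=ts(1))

    def test_zero_length_period_accepted(self, patient, level1_din):
        doc = new_document(patient, Period(ts(5), ts(5)), ts(6), level1_din)
        assert doc.header.export_period.start == doc.header.export_period.end

    def test_three_extensions_always_populated(self, minimal_doc):
        hdr = minimal_doc.header
        assert hdr.export_period is not None
        assert hdr.export_date is not None
        assert hdr.din_metadata is not None


class TestAddEntry:
    def test_lifestyle_entry_lands_in_lifestyle_section(self, minimal_doc):
        entry = entry_for_path("entry.lifestyle.mood", "e1", ts(3), Score(4))
        doc = add_entry(minimal_doc, entry)
        assert doc.header.section("lifestyle").entry_refs == ("e1",)
        assert doc.is_closed()

    def test_game_entry_lands_in_game_section(self, minimal_doc):
        entry = entry_for_path("entry.game.high-score", "e1", ts(3), Score(1200))
        doc = add_entry(minimal_doc, entry)
        assert doc.header.section("game").entry_refs == ("e1",)

    def test_wrong_system_code_rejected(self, minimal_doc):
        from ncdkit.model import Entry

        rogue = Entry(
            entry_id="e1",
            category="lifestyle",
            code=(terminology.canonical_uri("ncd-gamedata"), "achievement"),
            effective_time=ts(3),
            value=Text("x"),
        )
        with pytest.raises(CodeCategoryMismatchError):
            add_entry(minimal_doc, rogue)

    def test_operations_are_pure(self, minimal_doc):
        before = minimal_doc
        entry = entry_for_path("entry.lifestyle.mood", "e1", ts(3), Score(3))
        add_entry(minimal_doc, entry)
        assert minimal_doc == before
        assert minimal_doc.header.section("lifestyle").entry_refs == ()


class TestActors:
    def test_attach_practitioner_links_once(self, minimal_doc):
        pract = PractitionerRecord(resource_id="doc-1", pseudonym="dr")
        doc = attach_practitioner(minimal_doc, pract)
        assert doc.header.practitioner_ref == "doc-1"
        with pytest.raises(DuplicatePractitionerError):
            attach_practitioner(doc, PractitionerRecord(resource_id="doc-2", pseudonym="dr2"))

    def test_untagged_practitioner_attaches_without_error(self, minimal_doc):
        # construction never enforces profile conformance; validation does
        pract = PractitionerRecord(resource_id="doc-1", pseudonym="dr", profile_tag="")
        doc = attach_practitioner(minimal_doc, pract)
        assert doc.is_closed()

    def test_related_persons_are_zero_to_many(self, minimal_doc):
        doc = minimal_doc
        for i in range(3):
            doc = attach_related_person(
                doc, RelatedPersonRecord(resource_id=f"rp-{i}", pseudonym=f"p{i}")
            )
        assert len(doc.header.related_person_refs) == 3
        assert doc.is_closed()


class TestObligations:
    # independent oracle: the dependent-element mapping below was hand-built
    # from the archetype table before the resolver existed — a D element is
    # mandatory when the archetype's risk factor keys it OR the app itself
    # produces it (G8 records state of mind, so mood is mandatory there too)
    RISK_ORACLE = {
        "G1": {"entry.lifestyle.tobacco-use"},
        "G2": {"entry.clinical.nutrition-intake"},
        "G3": {"entry.clinical.nutrition-intake"},
        "G4": {"entry.clinical.nutrition-intake"},
        "G5": {"entry.clinical.nutrition-intake"},
        "G6": {"entry.lifestyle.mood"},
        "G7": {"entry.lifestyle.mood"},
        "G8": {
            "entry.clinical.blood-glucose",
            "entry.clinical.carbohydrate-intake",
            "entry.clinical.insulin-dosage",
            "entry.lifestyle.mood",
        },
    }

    @pytest.mark.parametrize("archetype_id", sorted(RISK_ORACLE))
    def test_d_activation_matches_hand_built_mapping(self, archetype_id):
        resolved = resolve_obligations(archetype_id).as_dict()
        active = {p for p, o in resolved.items() if o == "D-active"}
        assert active == self.RISK_ORACLE[archetype_id]

    def test_m_and_o_pass_through_unchanged(self):
        resolved = resolve_obligations("G8").as_dict()
        for rule in element_table():
            if rule.obligation in ("M", "O"):
                assert resolved[rule.path] == rule.obligation

    def test_resolution_is_total_over_element_table(self):
        paths = [r.path for r in element_table()]
        for archetype in archetype_registry().archetypes:
            resolved = resolve_obligations(archetype)
            assert [p for p, _ in resolved.obligations] == paths

    def test_unknown_archetype_id(self):
        with pytest.raises(UnknownArchetypeError):
            resolve_obligations("G9")


# property test: the closure invariant survives any construction sequence
_paths = [r.path for r in element_table() if r.category]


@st.composite
def _operations(draw):
    ops = draw(
        st.lists(
            st.one_of(
                st.tuples(st.just("entry"), st.sampled_from(_paths)),
                st.tuples(st.just("related"), st.integers(0, 99)),
                st.just(("practitioner",)),
            ),
            max_size=12,
        )
    )
    return ops


@settings(max_examples=40, deadline=None, derandomize=True)
@given(ops=_operations())
def test_closure_holds_after_any_operation_sequence(ops):
    doc = new_document(
        PatientRecord(resource_id="pat", pseudonym="p"),
        Period(ts(1), ts(31)),
        ts(31),
        DINMetadata(declared_level=1),
    )
    have_pract = False
    for i, op in enumerate(ops):
        if op[0] == "entry":
            value = Quantity(1.0, "u") if "clinical" in op[1] else Text("t")
            doc = add_entry(doc, entry_for_path(op[1], f"e{i}", ts(2), value))
        elif op[0] == "related":
            doc = attach_related_person(
                doc, RelatedPersonRecord(resource_id=f"rp{i}", pseudonym="r")
            )
        elif not have_pract:
            doc = attach_practitioner(
                doc, PractitionerRecord(resource_id="pr", pseudonym="d")
            )
            have_pract = True
    assert doc.is_closed()
    assert doc.header_first
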