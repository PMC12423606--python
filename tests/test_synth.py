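"""Archetype registry fidelity, generator realism, fault catalogue."""

import pytest

from ncdkit import synth
from ncdkit.errors import InvalidParamsError, UnknownArchetypeError, UnknownFaultError
from ncdkit.model import Quantity, Score, resolve_obligations
from ncdkit.synth import GeneratorParams, archetype_registry, generate_session, inject_fault
from ncdkit.validation import ISSUE_CATALOGUE, validate_document

# risk-factor column of the comparative-analysis table, cell for cell
EXPECTED_RISK = {
    "G1": "smoking",
    "G2": "nutrition",
    "G3": "nutrition",
    "G4": "nutrition",
    "G5": "nutrition",
    "G6": "mental-health",
    "G7": "mental-health",
    "G8": "hyperglycemia",
}


class TestRegistry:
    def test_exactly_eight_archetypes(self):
        assert archetype_registry().ids() == tuple(f"G{i}" for i in range(1, 9))

    def test_risk_factor_column(self):
        registry = archetype_registry()
        assert {a.archetype_id: a.main_risk_factor for a in registry.archetypes} == EXPECTED_RISK

    def test_named_rows(self):
        registry = archetype_registry()
        assert registry["G1"].name == "BreathIn"
        assert registry["G1"].app_type == "serious game"
        assert registry["G5"].app_type == "modification"
        assert registry["G8"].app_type == "gamified web application"
        assert registry["G8"].name == "DiaBeaThis"

    def test_registry_is_stable_across_calls(self):
        assert archetype_registry() is archetype_registry()

    def test_unknown_id(self):
        with pytest.raises(UnknownArchetypeError):
            archetype_registry()["G9"]


class TestGenerator:
    def test_g8_session_has_glucose_quantities_with_units(self, g8_doc):
        glucose = [
            e for e in g8_doc.data_entries("clinical") if e.code[1] == "2339-0"
        ]
        assert glucose
        for entry in glucose:
            assert isinstance(entry.value, Quantity)
            assert entry.value.unit == "mg/dL"

    def test_g7_session_carries_mood_scores_and_notes(self):
        doc = generate_session("G7", GeneratorParams(seed=3, n_entries=6))
        lifestyle_codes = {e.code[1] for e in doc.data_entries("lifestyle")}
        assert "mood" in lifestyle_codes
        mood = next(e for e in doc.data_entries("lifestyle") if e.code[1] == "mood")
        assert isinstance(mood.value, Score)

    def test_same_seed_same_document(self):
        params = GeneratorParams(seed=1, n_entries=5)
        assert generate_session("G8", params) == generate_session("G8", params)

    def test_different_seeds_differ(self):
        a = generate_session("G8", GeneratorParams(seed=1, n_entries=5))
        b = generate_session("G8", GeneratorParams(seed=2, n_entries=5))
        assert a != b

    def test_patients_are_pseudonymous(self, g8_doc):
        from ncdkit.model import PatientRecord

        patient = next(r for r in g8_doc.entries if isinstance(r, PatientRecord))
        assert patient.pseudonym.startswith("pseudonym-")

    @pytest.mark.parametrize("archetype_id", [f"G{i}" for i in range(1, 9)])
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_soundness_all_archetypes_twenty_seeds(self, archetype_id, seed):
        doc = generate_session(archetype_id, GeneratorParams(seed=seed, n_entries=8))
        report = validate_document(doc, resolve_obligations(archetype_id), 1)
        assert report.errors == ()

    def test_quantities_stay_in_documented_ranges_and_period(self):
        params = GeneratorParams(seed=5, n_entries=40)
        doc = generate_session("G8", params)
        period = params.resolved_period()
        ranges = {
            "2339-0": synth.GLUCOSE_RANGE_MG_DL,
            "9059-7": synth.CARBOHYDRATE_RANGE_G,
            "96596-5": synth.INSULIN_RANGE_IU,
        }
        for entry in doc.data_entries():
            assert period.contains(entry.effective_time)
            lo_hi = ranges.get(entry.code[1])
            if lo_hi and isinstance(entry.value, Quantity):
                assert lo_hi[0] <= entry.value.value <= lo_hi[1]
        moods = [e for e in doc.data_entries("lifestyle") if e.code[1] == "mood"]
        for mood in moods:
            assert 1 <= mood.value.value <= 5

    def test_too_few_entries_for_mandatory_coverage(self):
        with pytest.raises(InvalidParamsError):
            generate_session("G8", GeneratorParams(seed=1, n_entries=2))

    def test_invalid_params(self):
        with pytest.raises(InvalidParamsError):
            generate_session("G1", GeneratorParams(seed=1, n_entries=0))
        with pytest.raises(UnknownArchetypeError):
            generate_session("G9", GeneratorParams(seed=1, n_entries=5))


class TestFaults:
    def test_catalogue_has_at_least_six_kinds(self):
        assert len(synth.FAULT_CATALOGUE) >= 6
        kinds = {f.fault_kind for f in synth.FAULT_CATALOGUE}
        assert {
            "header-displaced",
            "dangling-reference",
            "missing-mandatory-element",
            "out-of-valueset-code",
            "untagged-practitioner",
            "din-element-removed",
        } <= kinds

    def test_expected_codes_exist_in_issue_catalogue(self):
        for fault in synth.FAULT_CATALOGUE:
            assert fault.expected_issue_code in ISSUE_CATALOGUE

    def test_injection_leaves_input_untouched(self, g8_doc):
        snapshot = g8_doc
        inject_fault(g8_doc, "din-element-removed")
        assert g8_doc == snapshot

    def test_unknown_fault(self, g8_doc):
        with pytest.raises(UnknownFaultError):
            inject_fault(g8_doc, "no-such-fault")
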