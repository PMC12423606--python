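"""Requirement catalog fidelity, RFC 2119 verdicts, key-area matrix."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncdkit.compliance import (
    AppManifest,
    KEY_AREAS,
    RequirementItem,
    audit_manifest,
    bct_coverage,
    key_area_matrix,
    load_manifest,
    load_requirement_catalog,
    packaged_manifests,
    rfc2119_verdict,
)
from ncdkit.errors import InvalidManifestError

# printed catalog, cell for cell: (level, type)
TABLE_EXPECTED = {
    "R01": ("must", "functional"),
    "R02": ("must", "functional"),
    "R03": ("should", "functional"),
    "R04": ("should", "nonfunctional"),
    "R05": ("may", "nonfunctional"),
    "R06": ("may", "nonfunctional"),
    "R07": ("may", "nonfunctional"),
    "R08": ("must", "nonfunctional"),
    "R09": ("may", "functional"),
    "R10": ("must", "nonfunctional"),
    "R11": ("should", "nonfunctional"),
    "R12": ("should", "nonfunctional"),
    "R13": ("must", "nonfunctional"),
    "R14": ("must", "functional"),
}


def saturated_manifest(**overrides):
    base = dict(
        app_id="GX",
        app_name="Test App",
        app_type="serious game",
        platform="Android",
        risk_factor="nutrition",
        bct_list=("self-monitoring-of-behavior", "feedback-on-behavior"),
        gamification_elements=("badges",),
        educational_content=True,
        usability_tested=True,
        graphics=True,
        audio=True,
        genre="platformer",
        intuitive_controls=True,
        social_features=("chat",),
        availability=True,
        cost="free",
        platform_barrier="low",
        clinician_involved=True,
        interoperable_export=True,
        key_area_evidence={k: "partial" for k in KEY_AREAS},
    )
    base.update(overrides)
    return AppManifest.model_validate(base)


class TestCatalog:
    def test_fourteen_requirements_cell_for_cell(self):
        catalog = load_requirement_catalog()
        assert len(catalog) == 14
        assert {i.req_id: (i.level, i.req_type) for i in catalog} == TABLE_EXPECTED

    def test_r14_wording_names_interoperable_extraction(self):
        r14 = load_requirement_catalog()[-1]
        assert "semantically interoperable" in r14.description


class TestVerdict:
    def test_all_fulfilled_is_compliant(self):
        report = audit_manifest(saturated_manifest())
        assert report.verdict == "compliant"
        assert all(s == "fulfilled" for _, s in report.per_requirement)

    def test_missing_must_is_noncompliant(self):
        report = audit_manifest(saturated_manifest(interoperable_export=False))
        assert report.status("R14") == "unfulfilled"
        assert report.verdict == "noncompliant"

    def test_missing_only_may_items_stays_compliant(self):
        report = audit_manifest(
            saturated_manifest(graphics=False, audio=False, genre="platformer")
        )
        assert report.verdict == "compliant"
        assert any("R05" in n for n in report.notes)

    def test_partial_should_is_conditionally_compliant(self):
        statuses = {rid: "fulfilled" for rid in TABLE_EXPECTED}
        statuses["R03"] = "partial"
        assert rfc2119_verdict(statuses) == "conditionally-compliant"

    def test_verdict_against_brute_force_oracle_on_subcatalog(self):
        # independent oracle: enumerate all 3^5 assignments over a reduced
        # catalog and apply the must/should/may rule literally
        sub = (
            RequirementItem("R01", "a", "must", "functional", "C2"),
            RequirementItem("R02", "b", "must", "functional", "C2"),
            RequirementItem("R03", "c", "should", "functional", "C2"),
            RequirementItem("R04", "d", "should", "nonfunctional", "C5"),
            RequirementItem("R05", "e", "may", "nonfunctional", "C5"),
        )

        def oracle(statuses):
            if any(statuses[i.req_id] != "fulfilled" for i in sub if i.level == "must"):
                return "noncompliant"
            if any(statuses[i.req_id] != "fulfilled" for i in sub if i.level == "should"):
                return "conditionally-compliant"
            return "compliant"

        for combo in itertools.product(
            ("fulfilled", "partial", "unfulfilled"), repeat=5
        ):
            statuses = dict(zip([i.req_id for i in sub], combo))
            assert rfc2119_verdict(statuses, sub) == oracle(statuses)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        statuses=st.fixed_dictionaries(
            {rid: st.sampled_from(("fulfilled", "partial", "unfulfilled")) for rid in TABLE_EXPECTED}
        ),
        upgraded=st.sampled_from(sorted(TABLE_EXPECTED)),
    )
    def test_upgrading_one_status_never_worsens_verdict(self, statuses, upgraded):
        order = {"compliant": 0, "conditionally-compliant": 1, "noncompliant": 2}
        before = rfc2119_verdict(statuses)
        ladder = {"unfulfilled": "partial", "partial": "fulfilled", "fulfilled": "fulfilled"}
        bumped = dict(statuses, **{upgraded: ladder[statuses[upgraded]]})
        assert order[rfc2119_verdict(bumped)] <= order[before]


class TestManifests:
    def test_packaged_fixtures_load_and_audit_deterministically(self):
        manifests = packaged_manifests()
        assert [m.app_id for m in manifests] == [f"G{i}" for i in range(1, 9)]
        for manifest in manifests:
            assert audit_manifest(manifest) == audit_manifest(manifest)

    def test_unknown_bct_code_rejected(self):
        with pytest.raises(InvalidManifestError):
            load_manifest("app_id: X\napp_name: X\napp_type: t\nplatform: p\n"
                          "risk_factor: r\nbct_list: [made-up-technique]\n"
                          "key_area_evidence: {C1: none, C2: none, C3: none, C4: none, C5: none, C6: none}\n")

    def test_partial_evidence_map_rejected(self):
        with pytest.raises(InvalidManifestError):
            load_manifest("app_id: X\napp_name: X\napp_type: t\nplatform: p\n"
                          "risk_factor: r\nkey_area_evidence: {C1: none}\n")


class TestBCTCoverage:
    def test_core_and_conditional_reported(self):
        manifest = saturated_manifest(bct_list=("self-monitoring-of-behavior",))
        coverage = dict(bct_coverage(manifest))
        core_present = [
            coverage[c]
            for c in (
                "information-about-health-consequences",
                "self-monitoring-of-behavior",
                "feedback-on-behavior",
            )
        ]
        assert core_present == [False, True, False]

    def test_empty_list_all_absent(self):
        manifest = saturated_manifest(bct_list=())
        assert all(not present for _, present in bct_coverage(manifest))


class TestMatrix:
    def test_fixture_matrix_reproduces_published_evaluation(self):
        matrix = key_area_matrix(packaged_manifests())
        frame = matrix.to_frame()
        # only none/partial ever appears; C1 and C3 columns are all none
        assert set(frame.values.ravel()) <= {"none", "partial"}
        assert (frame["C1"] == "none").all()
        assert (frame["C3"] == "none").all()
        assert (frame["C2"] == "partial").all()
        assert (frame["C5"] == "partial").all()
        assert (frame["C6"] == "partial").all()
        # the ecosystem column: only the game-appliance-integrated mod is partial
        assert frame["C4"].to_dict() == {
            "G1": "none", "G2": "none", "G3": "none", "G4": "none",
            "G5": "partial", "G6": "none", "G7": "none", "G8": "none",
        }

    def test_empty_input_empty_matrix(self):
        matrix = key_area_matrix([])
        assert matrix.rows == ()
        assert matrix.to_frame().empty

    def test_c2_cell_is_audit_derived(self):
        # a manifest fulfilling every C2-mapped requirement earns a full cell
        matrix = key_area_matrix([saturated_manifest()])
        assert matrix.cell("GX", "C2") == "full"
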