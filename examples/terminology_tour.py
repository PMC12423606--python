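"""Browse the packaged vocabularies and check value-set bindings.

Two implementation-guide code systems (game data, lifestyle data), the
behavior-change-technique vocabulary, and the three-level DIN metadata
scheme.
"""

from ncdkit import BindingSlot, din_required_elements, list_concepts, lookup_code, validate_binding
from ncdkit.terminology import LOINC_URI, canonical_uri

for system_id in ("ncd-gamedata", "ncd-lifestyle", "ncd-bct"):
    codes = [c.code for c in list_concepts(system_id)]
    print(f"{system_id}: {codes}")

mood = lookup_code("ncd-lifestyle", "mood")
print(f"\nlookup ncd-lifestyle/mood -> display={mood.display!r}: {mood.definition}")

slot = BindingSlot("lifestyle", "local", local_system_id="ncd-lifestyle")
uri = canonical_uri("ncd-lifestyle")
loinc = BindingSlot("lab", "loinc")
print(f"\nbinding (lifestyle, 'diary-entry'): {validate_binding(slot, uri, 'diary-entry')}")
print(f"binding (lifestyle, 'not-a-code'):  {validate_binding(slot, uri, 'not-a-code')}")
print(f"binding (loinc, '2339-0'):          {validate_binding(loinc, LOINC_URI, '2339-0')}")

for level in (1, 2, 3):
    print(f"\nDIN level {level} requires: {din_required_elements(level)}")

print()
print("# Lifestyle and game entries must be coded from their own code system; LOINC")
print("# bindings are checked by URI plus code shape only (no terminology server).")
print("# DIN levels are cumulative: each level contains every lower level's elements.")
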