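"""Generate seeded synthetic sessions for the eight application archetypes.

Each archetype (G1 BreathIn … G8 DiaBeaThis) produces the data elements the
real application records; the same seed always yields the same document.
"""

from ncdkit import GeneratorParams, archetype_registry, generate_session

registry = archetype_registry()
for archetype in registry.archetypes:
    doc = generate_session(archetype.archetype_id, GeneratorParams(seed=1, n_entries=6))
    kinds = {c: len(doc.data_entries(c)) for c in ("clinical", "game", "lifestyle")}
    print(
        f"{archetype.archetype_id} {archetype.name:<20} risk={archetype.main_risk_factor:<13}"
        f" entries: clinical={kinds['clinical']} game={kinds['game']} lifestyle={kinds['lifestyle']}"
    )

print()
print("# One export-session document per archetype, six entries each. The entry mix")
print("# mirrors what each application records: e.g. the hyperglycemia tracker (G8)")
print("# always carries glucose, carbohydrate, insulin, and mood entries because those")
print("# are dependent-mandatory for its archetype.")
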