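# ncdkit

An interoperability toolkit for **serious games and gamified applications that
prevent noncommunicable diseases (NCDs)** — diabetes, cardiovascular disease,
chronic respiratory disease — by targeting modifiable behavioral risk factors
(smoking, nutrition, mental health, hyperglycemia).

Such apps record valuable clinical, lifestyle, and game data (glucose
readings, cigarette counts, mood entries, achievements, high scores), but
each app speaks its own dialect, so none of it reaches electronic health
records. `ncdkit` implements a common document format for this data in the
style of an HL7 FHIR R5 implementation guide, plus the tooling around it:

- **model** — immutable document bundles: a composition header with three
  extensions (export period, export date, DIN serious-game metadata), links
  to patient / practitioner / related persons, and three data sections
  (clinical, game, lifestyle). Elements carry M/O/D obligations: mandatory,
  optional, or *dependent-mandatory* — mandatory only for application
  archetypes whose risk factor or produced data covers them.
- **terminology** — the two packaged code systems (`ncd-gamedata`:
  achievement, high-score, other; `ncd-lifestyle`: mood, alcohol-consumption,
  tobacco-use, diary-entry), a behavior-change-technique vocabulary, binding
  slots for SNOMED CT / LOINC (URI + code-shape checks, no terminology
  server), and the three-level DIN descriptive-metadata scheme.
- **validation** — a deterministic rule checker (bundle structure, reference
  closure, obligation satisfaction, value-set membership, practitioner
  profile restriction, DIN levels) with a closed issue catalogue.
- **io** — deterministic FHIR-style JSON document bundles; read ∘ write is
  the identity, unknown fields survive round-trips.
- **synth** — seeded synthetic sessions for the eight application archetypes
  the format was derived from (G1 BreathIn … G8 DiaBeaThis), plus a fault
  injector that breaks exactly one validation rule at a time.
- **compliance** — audits an application manifest against the 14-item
  requirement catalog with RFC 2119 semantics (must / should / may), checks
  recommended behavior-change-technique coverage, and aggregates the
  six-key-area (C1–C6) fulfillment matrix.

## Worked example

```python
from ncdkit import (GeneratorParams, generate_session, resolve_obligations,
                    validate_document, write_document, read_document)

doc = generate_session("G8", GeneratorParams(seed=1, n_entries=5))
report = validate_document(doc, resolve_obligations("G8"), din_level=1)
print(f"conformant={report.conformant}, errors={len(report.errors)}")
assert read_document(write_document(doc)) == doc
```

prints `conformant=True, errors=0`: a synthetic DiaBeaThis-style session
(glucose, carbohydrate, insulin, and mood entries are dependent-mandatory for
the hyperglycemia archetype, so all four are present) passes every rule and
survives serialization unchanged. Breaking it is caught — from
`examples/validate_and_inject_faults.py`:

```
clean G8 session: conformant=True, errors=0
header-displaced             -> DOC_FIRST_ENTRY_NOT_COMPOSITION     detected=True
dangling-reference           -> UNRESOLVED_REFERENCE                detected=True
missing-mandatory-element    -> MISSING_MANDATORY_ELEMENT           detected=True
out-of-valueset-code         -> CODE_NOT_IN_VALUESET                detected=True
untagged-practitioner        -> REFERENCE_PROFILE_VIOLATION         detected=True
din-element-removed          -> DIN_LEVEL_UNMET                     detected=True
section-category-mismatch    -> SECTION_CATEGORY_MISMATCH           detected=True
```

And `examples/audit_compliance.py` reproduces the published evaluation of
the eight analyzed apps — every app misses the interoperable-export *must*
(R14), so all verdicts are noncompliant, and the key-area matrix contains
only `none`/`partial` cells with C1 and C3 entirely `none`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch: generates a session per archetype,
validates it, round-trips it through JSON, verifies that every catalogued
fault is detected, audits the packaged manifests, and prints the key-area
matrix to stderr before writing its JSON result to `--out`.

See `docs/methods.md` for the data model, obligation semantics, generator
assumptions, and known limitations.
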