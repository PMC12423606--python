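# Methods

## The document model

The unit of exchange is a *document*: an immutable bundle whose first entry
is a composition attesting to the rest. The composition carries exactly
three extensions — the time period of the exported data, the export date,
and the DIN serious-game metadata — plus a subject link, an optional
practitioner link (cardinality 0..1, restricted to records tagged with the
NCD Practitioner profile), related-person links (0..*), and exactly three
sections: clinical, game, and lifestyle. Every reference the composition
makes must resolve inside the bundle (*closure*), which is what makes the
document self-contained and persistable.

All model values are frozen dataclasses; construction operations
(`new_document`, `add_entry`, `attach_practitioner`, …) are pure and return
new documents. Structural equality therefore doubles as the round-trip and
determinism test. A bundle with a *displaced* header remains representable
(the validator must be able to report it); a bundle with no header at all is
rejected at construction, mirroring the validator's `MALFORMED_DOCUMENT`
boundary.

### Obligations (M / O / D)

Elements carry one of three obligations: **M** (mandatory everywhere),
**O** (optional), **D** (dependent-mandatory: mandatory only for particular
applications). The packaged element table (`data/element_obligations.tsv`)
is deliberately a replaceable data file — the underlying guide does not
publish a complete machine-readable element list, so the table is the
package's explicit reconstruction.

`resolve_obligations` activates a D row when the archetype's main risk
factor matches the row's keying risk factor **or** the archetype explicitly
lists the element among its produced elements. Both routes matter: the
hyperglycemia archetype activates glucose/carbohydrate/insulin by risk
factor, and additionally mood by production (the app records state of mind
even though its risk factor is not mental health). D-active behaves exactly
as M during validation, D-inactive as O.

## Terminology

Two implementation-guide code systems are packaged (`ncd-gamedata`,
`ncd-lifestyle`), with tokens derived as lowercase kebab-case from their
display phrases ("high score" → `high-score`). "Others" is modeled as an
explicit `other` concept whose entries carry a free-text qualifier; badges
map to `achievement` and points to `other`. The BCT vocabulary
(`ncd-bct`) is restricted to the named recommended techniques, not the full
93-item taxonomy (external content). Canonical URIs live under a single
configurable base, default `urn:ncdkit:`, because no canonical URLs are
published.

External bindings (SNOMED CT, LOINC) are validated by well-known system URI
plus syntactic code shape only — no terminology server, no distributed
content. Consequently the specific LOINC tokens in the element table are
*placeholders in valid LOINC shape* (glucose `2339-0` is the well-known
code; others are illustrative) and are replaceable via the data file.

### DIN metadata

The DIN serious-game metadata scheme has three nested levels; level 1
(core) is required, levels 1+2 preferred, level 3 optional. The standard's
concrete element names are not reproduced here; the packaged scheme (title,
publisher, language, platform, characterizing-goal, target-group; + genre,
bct-list, play-duration; + application-profile) is a placeholder whose
*nesting semantics* are the tested contract, replaceable via
`data/din_scheme.tsv`. The metadata is carried structurally and rendered to
the single free-text extension on export (the exchange shape), because the
string-valued form is explicitly a known weakness of the format being
modeled; `din_as_text=False` emits the structured form instead.

## Validation

Seven rules (see `validation.validate_document`); all findings are
reported, never thrown. Severity policy: structural, obligation, binding,
and profile violations are errors; an absent level-2 DIN element when
checking level 1 is informational ("preferred, not required"). Issues are
de-duplicated and sorted by (path, code), so equal inputs give byte-equal
reports. Every emitted code belongs to a closed, documented catalogue.

## Synthetic sessions

The generator emulates one export session per archetype of the eight
analyzed applications, with the produced-element lists reconstructed from
their descriptions (the four nutrition titles are narrative-only and flagged
`best_effort` in the registry). Defaults: a one-month export period
(January 2024, UTC), 10 entries, a pseudonymous patient, and a tagged
practitioner. One entry per D-active element is emitted first — this is
what makes every generated document conformant by construction — so
`n_entries` must be at least the archetype's D-active count (e.g. 4 for the
hyperglycemia archetype); fewer raises `INVALID_PARAMS` rather than
silently generating a non-conformant document.

Measurement ranges are artifact choices, documented as named constants:
glucose 40–400 mg/dL, carbohydrates 0–150 g, insulin 0–30 IU, activity
5–180 min, mood 1–5 (the emoji picker maps onto this ordinal scale, with
the emoji kept as display text), stress 0–40, meals 50–1500 kcal,
cigarettes 0–40/day, alcohol 0–10 units, high scores up to 100 000. They
aim for physiological plausibility, not longitudinal realism: entries are
independent draws, so the generator exercises format and rules, **not**
clinical time-series structure. A green validator or round-trip test
establishes conformance and losslessness of the format — nothing about
behavioral or clinical fidelity.

Fault injection perturbs a document minimally so that exactly one targeted
rule breaks; the input is never mutated, so conformance is restored by
simply reusing (or regenerating) the original.

## Compliance auditing

The 14-item requirement catalog ships as data with its printed levels and
types. Two editorial tables are layered on top, both documented here
because the source material names requirements without operational criteria:

- **field → requirement mapping**: which manifest capability satisfies which
  requirement (e.g. R01 needs a non-empty BCT list, R14 the interoperable
  export flag). Genre scoring is three-valued: a recommended genre
  (platformer, adventure) fulfills R07, any declared genre is partial,
  none is unfulfilled.
- **requirement → key area**: R01–R03, R07, R09 → C2; R04–R06, R08 → C5;
  R10–R12 → C4; R13 → C1; R14 → C3.

Verdict rule: any not-fulfilled *must* ⇒ noncompliant; otherwise any
not-fulfilled *should* ⇒ conditionally-compliant; otherwise compliant
(*may* items never worsen the verdict). The status scale
{fulfilled, partial, unfulfilled} extends the published none/partial cell
vocabulary with a `full` level so new applications can score better than
the analyzed ones.

Key areas C1 and C3–C6 are not machine-checkable from a manifest, so matrix
cells come from declared evidence; only C2 is recomputed from the audit
(all C2 requirements fulfilled ⇒ full, any progress ⇒ partial, else none).
The packaged G1–G8 manifests encode the published evaluation directly; the
judgment of what counted as "partial" there is editorial and inherited.

## Design choices and limitations

- **No CLI.** The toolkit is consumed from Python; `examples/` carries one
  narrative script per capability. Report serialization (`to_text`,
  `to_json`, `to_csv`) covers the CI-integration role a CLI would have had.
- Serialization is JSON-only by design (no XML), deterministic
  (byte-identical for equal inputs), and lossless for unknown fields via an
  opaque side-channel.
- The validator checks this guide's rule set only; it is not a general FHIR
  R5 structural validator.
- Timestamps are timezone-aware ISO-8601 throughout; naive datetimes are
  rejected at construction.
- Whether insulin dosage is better modeled as a medication resource than an
  observation is an open modeling question; it is an observation-shaped
  entry here for uniformity across entry kinds.
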