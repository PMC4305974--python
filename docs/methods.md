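# Methods

## The reference model

Every anatomic-pathology observation is represented as a postcoordinated
expression over a concept graph:

```
GenericObservation = Context(locator?, problem?, method?)
                   + Target (exactly one)
                   + Property (exactly one)
                   + Qualifier* (canonical set)
                   + Value? (coded | quantity+unit)
```

Concepts are either SNOMED CT codes or local tokens. The graph stores four
typed, directed relationships — `IS-A` and `PART-OF` (both kept acyclic, an
edge that would close a cycle is refused with the offending path),
`HAS-TARGET` (property → the entity it is about) and `IS-QUALIFIER-OF`
(qualifier → what it refines). `IS-TARGET-OF` is only the inverse *view* of
`HAS-TARGET`; storing one canonical direction avoids double bookkeeping.

### Permissible values without a SNOMED release

The permissible-value tables for targets, properties and qualifiers are
packaged as plain transcriptions (designation, SNOMED code, axis,
approximate-flag). The "permissible values, their descendants included" rule
is made executable without ingesting a SNOMED CT release by two devices:

1. each table row becomes a role root; a candidate fills a role iff some
   root of that role lies in the candidate's reflexive-transitive `IS-A`
   closure (so each root is itself permissible);
2. the printed "(SNOMED CT axis)" annotations become `IS-A` links to local
   axis-root concepts (`body structure (axis)`, `qualifier value (axis)`,
   ...), which also gives locators a validation target: a locator must sit
   under the body-structure axis root.

Codes the source tables print in parentheses (the neighborhood-relationship
and treatment-effect properties) are loaded with `approximate=True`; they
validate and count as mapped for coverage, the flag merely records the
uncertainty. Rows printed without a code (`Focality`, `specialAttributes`)
become local concepts so they stay usable as qualifiers. `specialAttributes`
is an open enumeration seeded with *nearest, biggest, most, least, smallest*
plus *largest*; observation methods (`ObservedByMicroscopicInvestigation`,
`ObservedByMacroscopicInvestigation`) hang under a local `observationMethod`
root and live in the expression's Context rather than the general qualifier
list, keeping how-it-was-seen apart from what-was-seen. One SNOMED code
(49755003) legitimately appears both as the target *Lesion* and as the
qualifier root *abnormalStructure*; the graph keys concepts by
(namespace, code) and keeps the second designation as an alias.

### Canonicalization and subsumption

Qualifier order carries no meaning, so expressions are canonicalized by
sorting qualifiers on `(namespace, code)` and dropping duplicates; equality
of expressions is therefore order-insensitive, and all serializations (JSON,
XML, SCG) round-trip to the same canonical expression. `subsumes(a, b)`
holds iff each of b's target/property/locator/problem is a descendant (or
equal) of a's corresponding slot — an absent slot in `a` is most-general,
standard postcoordination semantics — and each qualifier of `a` subsumes
some qualifier of `b`. This makes subsumption a preorder (reflexive,
transitive), which the tests verify against a slot-wise brute-force oracle.

## Decomposition and the genericity criterion

Interface names follow an `Organ-Problem-Element` grammar with `-` as the
context delimiter. Because hyphens also occur inside element names
(`PD-L1 expression`, `ICD-O classification`), a leading segment is consumed
as context only when it is in the organ lexicon (and the next one only when
it is in the problem lexicon); commas and spaces are never delimiters. The
problem lexicon also normalises interface spellings to problem organizers
("In situ neoplasm" → *non-invasive tumor*, "Invasive neoplasm" →
*invasive tumor*).

The stripped element is matched against the packaged 17-row equivalence
table. Matching is token-based and longest-pattern-first (so `Macroscopic
type` reaches its own row, not the generic `type` pattern of the
classification row); equally long competing patterns are resolved by
lexicographic order of the generic designation, with a warning. Each row
carries a composition recipe (target, property, method, base qualifiers);
special-attribute tokens found in the element name (*largest, closest, ...*)
add qualifiers, and the parsed context supplies locator and problem. Rows
for staging/grading/classification, markers and procedures are
*parameterized families*: many interface elements (pT, pN, Gleason score,
Estrogen receptor, ...) share one row, so for those families the recovered
generic-element identity is the element name itself, while for the remaining
rows it is the row's generic designation (Diameter, Weight, ...). A
`Focality` equivalence row aliases the qualifier of the same name (recipe:
*Number* of *Lesion* qualified by *Focality*): the concept is genuinely both
an element and a qualifier.

The decisive genericity question is answered by the **value-set-uniqueness
criterion**: an element is generic iff every occurrence across all
(organ, problem) contexts carries the identical value set; otherwise a
specific per-context term with its own value set is required. A
single-occurrence element is vacuously generic; `classify_genericity`
exposes a policy flag to invert that reading. `registry_stats` tallies the
breakdown (observations vs procedures, generic-mapped vs specific templates,
distinct generic elements per family, distinct locator organs) plus a
SNOMED-mapping coverage percentage whose denominator is *distinct generic
elements*, an element counting as mapped when its recipe's target and
property are both SNOMED-coded (approximate included). On the packaged
recipes every element is coded, so the default profile reports 100.0; the
standalone `snomed_coverage` helper computes the same one-decimal percentage
over any concept collection (the packaged tables themselves: 37 of 39 rows
coded, 94.9).

## The synthetic registry and what it does (not) show

Real interface registries ship as spreadsheets that cannot be redistributed
here, so the generator rebuilds one from a declarative composition profile.
The default profile reconstructs the published registry *composition*:

| family                            | elements | contexts each | templates |
|-----------------------------------|---------:|--------------:|----------:|
| core-generic                      |        9 |            15 |       135 |
| staging/grading/classification    |       28 |             8 |       224 |
| marker                            |       15 |             6 |        90 |
| procedure-row observation         |        1 |             1 |         1 |
| specific                          |        8 |        2 (×7), 3 (×1) | 17 |
| procedures                        |        — |             — |        21 |
| **total**                         |   **53** |               |   **488** |

giving 467 observations + 21 procedures, 53 distinct generic elements
(28 + 15 + 9 + 1 — the one element outside the three families matches the
equivalence table's *Procedure* row while being an observation, which is
why the family counts sum to 52 ≤ 53) and 17 specific templates across 20
organs. The organ list, the element names within the staging/marker/specific
families, the expansion multiplicities and all value-set contents are
**reconstruction, not source content**; value-set contents are deliberately
minimal because analysing them is out of scope. Contexts are assigned by
striding through the organ list with stride 7 (coprime to 20, so every
element sees distinct organs and the registry covers all 20) while
alternating the two problem organizers. Generic-family elements keep an
identical value set in every context; each specific element gets one extra
value-set member in its first context — the minimal violation of the
uniqueness criterion. OIDs are allocated sequentially under the
documentation arc `2.999.1.4`; the seed only shuffles row order.

The decomposer sees nothing but names and value sets, so the
generator → decomposer identity (every generic-family template decomposes to
its source element, every specific one is rejected) is a real round-trip
check of the grammar, the pattern matcher and the classifier. What passing
does **not** show: robustness to the messiness of real registries —
inconsistent spellings, missing delimiters, organ names absent from the
lexicon, value sets differing only by synonymy. Those would surface as
`specific` verdicts or skipped rows, which is the designed failure mode
(conservative, never silently generic).

## Serializations

- **Registry dialect**: tab-delimited UTF-8, header required, columns
  `oid, name, organ, problem, category, value_set`, value-set members
  separated by `|` (commas occur inside names). Rows with malformed OIDs go
  to an error report instead of being dropped.
- **XML**: artifact-defined, CDA-compatible conventions without claiming CDA
  conformance — `code/@code` with `codeSystem` 2.16.840.1.113883.6.96 for
  SNOMED, local concepts under the reserved arc 2.999.1.1; the property
  element carries `relationship="HAS-TARGET"` and points at the target
  element, qualifier/method elements carry `relationship="IS-QUALIFIER-OF"`;
  locator and problem organizer are sibling context elements. Writers are
  byte-deterministic and every document is validated against the shipped
  XSD on write.
- **SCG dialect**: focus concept = target; the refinement block opens with
  the bare property term followed by keyed `qualifier/method/locator/
  problem/value` pairs; local concepts carry the `PL-` prefix. The property
  is always rendered (it is a mandatory slot), so even a context-free
  expression has a refinement block: `123038009 |specimen| : 272102008
  |weight|`. Designations containing `|` or `,` are outside the dialect;
  concept identity is carried by the code, designations are display only.

## Numerical and degenerate-input choices

- Coverage percentages are rounded to one decimal; exact-duplicate concepts
  are de-duplicated first, but a code reused under a distinct designation
  counts per row (matching a hand count of the tables).
- Empty registries yield an all-zero report; coverage of an empty concept
  collection raises rather than returning a fake 0.
- Duplicate edge insertion is idempotent (table loaders re-read shared
  parents); duplicate qualifiers are normalised silently; role violations
  are aggregated so a caller sees every problem at once.
- `registry_stats` is invariant to registry order and value-set member
  order, and deterministic for a fixed registry.

## Known limitations

- No SNOMED CT release ingestion, ECL evaluation or description-logic
  classification; subsumption is exactly the four-relationship closure
  semantics above.
- Procedures are a classification category only; they are counted, never
  decomposed.
- The published two-thirds SNOMED-coverage figure for generic interface
  terms has an ambiguous denominator and is intentionally not reproduced;
  the package reports coverage only for quantities it can define precisely.
- The equivalence table's pattern lists are curated data; genuinely novel
  element phrasings fall back to `specific`, never to a guessed mapping.
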