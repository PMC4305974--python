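# pathterm

A reference-model terminology engine for **generic observations in anatomic
pathology structured reports**.

Interface terminologies for pathology reporting (checklist-driven term
collections such as PathLex, carrying APSR template OIDs) are
*precoordinated*: they enumerate one term per organ / disease / feature
combination, e.g. `Breast-In situ neoplasm-Lesion size, largest dimension`.
That keeps data entry easy but makes the terminology explode combinatorially
and hides the relationships between terms. A *reference-model* (concept-based,
postcoordinated) approach expresses the same content from a small set of
generic building blocks: every anatomic-pathology observation

- occurs in a **context** — a locator (organ/body site), a pathological
  **problem organizer** (e.g. invasive vs non-invasive tumor) and an
  observation **method**, and
- consists of a **target** of observation (specimen, lesion, nucleus,
  margin, ...), a **property** of observation (diameter, grade, colour, ...)
  and additional **qualifiers** (laterality, invasiveness, "largest", ...),
  optionally closed by a coded or quantitative value.

`pathterm` implements this model end to end, for terminology engineers and
health-informatics developers who need to analyse, migrate or generate
structured-reporting terminologies:

- **ontology** (`pathterm.ontology`) — a concept graph over SNOMED CT codes
  and local tokens with exactly four relationship types (`IS-A`, `PART-OF`,
  `HAS-TARGET`, `IS-QUALIFIER-OF`; `IS-TARGET-OF` is exposed as the inverse
  view of `HAS-TARGET`), acyclicity checking, transitive closures, and
  "descendants included" permissible-value queries;
- **expressions** (`pathterm.model`) — composition and validation of
  postcoordinated observations, canonicalization, and subsumption
  (`a` subsumes `b` iff every slot of `b` specialises the corresponding slot
  of `a` and `a`'s qualifiers are a subset of `b`'s under `IS-A` matching);
- **decomposition** (`pathterm.decomposition`) — parsing
  `Organ-Problem-Element` interface names, mapping elements to generic
  equivalents through a packaged equivalence table, classifying elements as
  *generic* or *specific* by the **value-set-uniqueness criterion** (a term
  is generic iff it carries the identical value set in every context in
  which it occurs), registry breakdown statistics and SNOMED mapping
  coverage;
- **serializations** (`pathterm.io_formats`) — a tab-delimited registry
  dialect, canonical JSON, HL7-template-style XML (validated against a
  shipped XSD, with relationships carried as `HAS-TARGET` /
  `IS-QUALIFIER-OF` attributes) and a SNOMED compositional-grammar (SCG)
  dialect;
- **synthetic registries** (`pathterm.fixtures`) — a generator that emits a
  full precoordinated registry from a declarative composition profile, so
  the whole pipeline is testable without any proprietary spreadsheet;
- a **CLI** (`pathterm`) with subcommands `generate`, `decompose`, `compose`,
  `stats`, `coverage`, `export-xml`, `export-scg`.

## Worked example

The precoordinated interface term
`Breast-In situ neoplasm-Lesion size, largest dimension` is one organ- and
disease-bound spelling of a single generic observation. Decompose it:

```sh
$ printf 'oid\tname\torgan\tproblem\tcategory\tvalue_set\n1.3.6.1.4.1.49376.1.8.1.4.442\tBreast-In situ neoplasm-Lesion size, largest dimension\t\t\tobservation\t\n' > demo.tsv
$ pathterm decompose demo.tsv
oid	name	verdict	element	generic_element	family	reason
1.3.6.1.4.1.49376.1.8.1.4.442	Breast-In situ neoplasm-Lesion size, largest dimension	generic	Diameter	Diameter	core_generic
```

The verdict `generic` means the term reduces to the generic element
**Diameter**: the property *Diameter* (SNOMED 81827009) of the target
*Lesion* (49755003), qualified as *ObservedByMicroscopicInvestigation* and
*Largest*, with locator *breast* and problem organizer *non-invasive tumor*.
The same expression composed directly and rendered in the SCG dialect:

```sh
$ pathterm compose --target Lesion --property Diameter --qualifier Largest \
    --locator Breast --problem "non-invasive tumor" \
    --method ObservedByMicroscopicInvestigation --format scg
49755003 |lesion| : 81827009 |diameter|, qualifier = PL-largest |largest|, method = PL-ObservedByMicroscopicInvestigation |observedbymicroscopicinvestigation|, locator = PL-breast |breast|, problem = PL-non-invasive-tumor |non-invasive tumor|
```

(`PL-` is the reserved prefix for local, non-SNOMED concepts.)

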