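"""Decomposition of precoordinated interface terms into generic expressions.

Interface terminologies for structured pathology reporting enumerate one
term per organ/problem/feature combination ("Breast-In situ neoplasm-Lesion
size, largest dimension"). This module parses such names, matches the
feature part against the packaged equivalence table (interface element ->
generic reference element, with a composition recipe), builds the canonical
postcoordinated expression, classifies elements as generic or specific by
the value-set-uniqueness criterion, and tallies registry statistics
including SNOMED mapping coverage.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import (
    ConfigurationError,
    CoverageUndefinedError,
    MissingConceptError,
    NameParseError,
    NotFoundError,
)
from .model import Context, GenericObservation, Property, Qualifier, Target, compose
from .ontology import ConceptRef, OntologyGraph

OID_RE = re.compile(r"^\d+(\.\d+)+$")


class Category(str, Enum):
    OBSERVATION = "observation"
    PROCEDURE = "procedure"


class Family(str, Enum):
    """Generic-element families used in the registry breakdown."""

    CORE_GENERIC = "core_generic"
    STAGING_GRADING_CLASSIFICATION = "staging_grading_classification"
    MARKER = "marker"
    PROCEDURE = "procedure"


#: Families whose equivalence rows are parameterized (many interface elements
#: per row); the generic-element identity is then the element name itself.
PARAMETERIZED_FAMILIES = frozenset(
    {Family.STAGING_GRADING_CLASSIFICATION, Family.MARKER, Family.PROCEDURE}
)


class Verdict(str, Enum):
    GENERIC = "generic"
    SPECIFIC = "specific"
    PROCEDURE = "procedure"


@dataclass(frozen=True)
class PrecoordinatedTerm:
    """One interface-terminology row (a template)."""

    oid: str
    name: str
    organ: str | None = None
    problem: str | None = None
    category: Category = Category.OBSERVATION
    value_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not OID_RE.match(self.oid):
            raise ValueError(f"not a dotted-decimal OID: {self.oid!r}")
        if not self.name.strip():
            raise ValueError("term name must be nonempty")


@dataclass(frozen=True)
class Recipe:
    """How a generic element is expressed in the reference model."""

    target: str
    property: str
    method: str | None = None
    qualifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class EquivalenceRow:
    oid: str
    pattern: str
    generic_element: str
    family: Family
    is_example: bool
    extra_patterns: tuple[str, ...]
    recipe: Recipe
    note: str = ""

    def patterns(self) -> tuple[str, ...]:
        return (self.pattern,) + self.extra_patterns


def _tokens(text: str) -> tuple[str, ...]:
    return tuple(t for t in re.split(r"[^0-9A-Za-z]+", text.casefold()) if t)


def _contains_token_seq(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0:
        return False
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


class EquivalenceTable:
    """The interface-element -> generic-element mapping.

    Matching is token-based (an element name matches a pattern when the
    pattern's tokens occur contiguously among the name's tokens,
    case-insensitively), longest pattern first; ties between equally long
    patterns are broken by lexicographic order of the generic designation,
    with a warning.
    """

    def __init__(self, rows: Sequence[EquivalenceRow]):
        designations = [r.generic_element for r in rows]
        if len(set(designations)) != len(designations):
            raise ValueError("generic element designations must be unique")
        self.rows = tuple(rows)
        self._by_element = {r.generic_element: r for r in rows}
        # precompute (pattern tokens, row), longest first
        self._patterns: list[tuple[tuple[str, ...], str, EquivalenceRow]] = []
        for row in rows:
            for pat in row.patterns():
                self._patterns.append((_tokens(pat), pat, row))
        self._patterns.sort(key=lambda t: (-len(t[0]), -len(t[1]), t[2].generic_element))

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, generic_element: str) -> EquivalenceRow:
        return self._by_element[generic_element]

    def match(self, element: str) -> tuple[EquivalenceRow, str] | None:
        toks = _tokens(element)
        best: list[tuple[tuple[str, ...], str, EquivalenceRow]] = []
        for pat_toks, pat, row in self._patterns:
            if _contains_token_seq(toks, pat_toks):
                if not best:
                    best.append((pat_toks, pat, row))
                elif len(pat_toks) == len(best[0][0]) and len(pat) == len(best[0][1]):
                    best.append((pat_toks, pat, row))
                else:
                    break  # sorted longest-first; later ones are shorter
        if not best:
            return None
        if len({r.generic_element for _, _, r in best}) > 1:
            names = sorted(r.generic_element for _, _, r in best)
            warnings.warn(
                f"element {element!r} matches equally specific patterns for "
                f"{names}; choosing {names[0]!r}",
                stacklevel=2,
            )
        _, pat, row = best[0]
        return row, pat


@dataclass(frozen=True)
class NameGrammar:
    """"Organ-Problem-Element" naming grammar of the interface dialect.

    ``organ_lexicon`` disambiguates delimiters occurring inside element
    names: a leading segment is a context segment only when it is a known
    organ. ``problem_lexicon`` maps interface problem tokens (e.g. "In situ
    neoplasm") to problem-organizer designations ("non-invasive tumor").
    ``special_attributes`` maps element-name tokens to special-attribute
    qualifier designations ("largest", "nearest", ...).
    """

    delimiter: str = "-"
    organ_lexicon: frozenset[str] = frozenset()
    problem_lexicon: dict[str, str] = field(default_factory=dict)
    special_attributes: dict[str, str] = field(default_factory=dict)

    def normalize_organ(self, token: str) -> str | None:
        return token if token.casefold() in self.organ_lexicon else None


@dataclass(frozen=True)
class ParsedName:
    organ: str | None
    problem: str | None
    element: str


def parse_name(name: str, grammar: NameGrammar) -> ParsedName:
    """Split an interface term name into (organ, problem, element).

    At most two leading context segments are recognised; the first only when
    it is in the organ lexicon, the second only when it is in the problem
    lexicon. Everything else (including further delimiters) stays in the
    element. Raises :class:`NameParseError` on empty or all-delimiter names.
    """
    if not name or not name.strip():
        raise NameParseError("empty term name")
    segments = [s.strip() for s in name.split(grammar.delimiter)]
    if not any(segments):
        raise NameParseError(f"name is all delimiters: {name!r}")
    organ: str | None = None
    problem: str | None = None
    rest = segments
    if len(segments) > 1 and segments[0].casefold() in {o.casefold() for o in grammar.organ_lexicon}:
        organ = segments[0]
        rest = segments[1:]
        if len(rest) > 1 and rest[0].casefold() in {
            p.casefold() for p in grammar.problem_lexicon
        }:
            problem = rest[0]
            rest = rest[1:]
    element = grammar.delimiter.join(rest).strip()
    if not element:
        raise NameParseError(f"no element part in {name!r}")
    return ParsedName(organ=organ, problem=problem, element=element)


@dataclass(frozen=True)
class DecompositionResult:
    verdict: Verdict
    term: PrecoordinatedTerm
    expression: GenericObservation | None = None
    matched_generic_element: str | None = None
    matched_row: str | None = None
    family: Family | None = None
    unmatched_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.verdict is Verdict.GENERIC) != (self.expression is not None):
            raise ValueError("expression present iff verdict is generic")


def _resolve(graph: OntologyGraph, designation: str, what: str) -> ConceptRef:
    try:
        return graph.by_designation(designation)
    except MissingConceptError as exc:
        raise ConfigurationError(f"{what} {designation!r} is not registered") from exc


def decompose_term(
    term: PrecoordinatedTerm,
    eq: EquivalenceTable,
    graph: OntologyGraph,
    grammar: NameGrammar,
) -> DecompositionResult:
    """Map one precoordinated term to its generic expression, if any.

    Procedures are classified, not decomposed. For observations the parsed
    element is matched against the equivalence table; on a match the row's
    recipe supplies target/property/method/base qualifiers, special-attribute
    tokens found in the element name add qualifiers, and the parsed context
    supplies locator and problem organizer.
    """
    if term.category is Category.PROCEDURE:
        return DecompositionResult(verdict=Verdict.PROCEDURE, term=term)
    parsed = parse_name(term.name, grammar)
    matched = eq.match(parsed.element)
    if matched is None:
        return DecompositionResult(
            verdict=Verdict.SPECIFIC,
            term=term,
            unmatched_reason=f"element {parsed.element!r} matches no equivalence pattern",
        )
    row, _pattern = matched

    target = Target(_resolve(graph, row.recipe.target, "recipe target"))
    prop = Property(_resolve(graph, row.recipe.property, "recipe property"))
    qualifiers = [
        Qualifier(_resolve(graph, q, "recipe qualifier")) for q in row.recipe.qualifiers
    ]
    for token in _tokens(parsed.element):
        special = grammar.special_attributes.get(token)
        if special is not None:
            qualifiers.append(Qualifier(_resolve(graph, special, "special attribute")))
    method = (
        Qualifier(_resolve(graph, row.recipe.method, "recipe method"))
        if row.recipe.method
        else None
    )
    locator = _resolve(graph, parsed.organ, "organ") if parsed.organ else None
    problem = None
    if parsed.problem is not None:
        designation = grammar.problem_lexicon[parsed.problem.casefold()]
        problem = _resolve(graph, designation, "problem organizer")

    expr = compose(
        graph,
        target=target,
        property=prop,
        qualifiers=qualifiers,
        context=Context(locator=locator, problem=problem, method=method),
    )
    generic_element = (
        parsed.element if row.family in PARAMETERIZED_FAMILIES else row.generic_element
    )
    return DecompositionResult(
        verdict=Verdict.GENERIC,
        term=term,
        expression=expr,
        matched_generic_element=generic_element,
        matched_row=row.generic_element,
        family=row.family,
    )


def classify_genericity(
    element: str,
    registry: Iterable[PrecoordinatedTerm],
    grammar: NameGrammar,
    *,
    single_occurrence_generic: bool = True,
) -> Verdict:
    """Classify an element by value-set uniqueness across its contexts.

    An element is *generic* when every occurrence across all (organ, problem)
    contexts carries the identical value set (compared as order-insensitive
    sets); otherwise it is *specific* and needs its own per-context term. A
    single occurrence is vacuously generic (set
    ``single_occurrence_generic=False`` to invert that policy).
    """
    want = element.casefold()
    value_sets: list[frozenset[str]] = []
    for term in registry:
        if term.category is Category.PROCEDURE:
            continue
        parsed = parse_name(term.name, grammar)
        if parsed.element.casefold() == want:
            value_sets.append(frozenset(term.value_set))
    if not value_sets:
        raise NotFoundError(f"element {element!r} does not occur in the registry")
    if len(value_sets) == 1 and not single_occurrence_generic:
        return Verdict.SPECIFIC
    return Verdict.GENERIC if len(set(value_sets)) == 1 else Verdict.SPECIFIC


@dataclass(frozen=True)
class StatsReport:
    """Registry breakdown in the shape the reference-model analysis reports."""

    total_templates: int
    observations: int
    procedures: int
    generic_mapped: int  # observation templates with a generic equivalent
    specific_terms: int  # observation templates left specific
    generic_elements: int  # distinct generic elements recovered
    core_generic_terms: int
    staging_grading_classification_terms: int
    marker_terms: int
    organs: int
    coverage_percent: float
    skipped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.observations + self.procedures != self.total_templates:
            raise ValueError("observations + procedures must equal total")
        if self.generic_mapped + self.specific_terms != self.observations - len(self.skipped):
            raise ValueError("generic-mapped + specific must cover the observations")
        fam = (
            self.core_generic_terms
            + self.staging_grading_classification_terms
            + self.marker_terms
        )
        if fam > self.generic_elements:
            raise ValueError("family counts exceed distinct generic elements")
        if not (0.0 <= self.coverage_percent <= 100.0):
            raise ValueError("coverage must be a percentage")

    def to_dict(self) -> dict:
        return {
            "total_templates": self.total_templates,
            "observations": self.observations,
            "procedures": self.procedures,
            "generic_mapped": self.generic_mapped,
            "specific_terms": self.specific_terms,
            "generic_elements": self.generic_elements,
            "core_generic_terms": self.core_generic_terms,
            "staging_grading_classification_terms": self.staging_grading_classification_terms,
            "marker_terms": self.marker_terms,
            "organs": self.organs,
            "coverage_percent": self.coverage_percent,
            "skipped": list(self.skipped),
        }


def _element_is_mapped(row: EquivalenceRow, graph: OntologyGraph) -> bool:
    """A generic element counts as SNOMED-mapped when its recipe's target and
    property concepts both carry SNOMED codes (approximate included)."""
    from .ontology import Namespace

    try:
        target = graph.by_designation(row.recipe.target)
        prop = graph.by_designation(row.recipe.property)
    except MissingConceptError:
        return False
    return target.namespace is Namespace.SNOMED and prop.namespace is Namespace.SNOMED


def registry_stats(
    registry: Sequence[PrecoordinatedTerm],
    eq: EquivalenceTable,
    graph: OntologyGraph,
    grammar: NameGrammar,
) -> StatsReport:
    """Decompose every registry entry and tally the breakdown.

    Malformed entries (unparseable names) are collected in ``skipped`` rather
    than aborting the run. The family counters count *distinct generic
    elements*, as does the coverage denominator.
    """
    total = len(registry)
    procedures = 0
    generic_mapped = 0
    specific = 0
    skipped: list[str] = []
    elements: dict[str, Family] = {}
    element_rows: dict[str, EquivalenceRow] = {}
    organs: set[str] = set()

    for term in registry:
        try:
            parsed = parse_name(term.name, grammar)
        except NameParseError:
            skipped.append(term.oid)
            continue
        if parsed.organ is not None:
            organs.add(parsed.organ.casefold())
        result = decompose_term(term, eq, graph, grammar)
        if result.verdict is Verdict.PROCEDURE:
            procedures += 1
        elif result.verdict is Verdict.GENERIC:
            generic_mapped += 1
            assert result.matched_generic_element is not None
            assert result.family is not None and result.matched_row is not None
            elements[result.matched_generic_element] = result.family
            element_rows[result.matched_generic_element] = eq.row(result.matched_row)
        else:
            specific += 1

    n_elements = len(elements)
    mapped = sum(1 for row in element_rows.values() if _element_is_mapped(row, graph))
    coverage = round(100.0 * mapped / n_elements, 1) if n_elements else 0.0
    fam_counts = {f: sum(1 for v in elements.values() if v is f) for f in Family}

    return StatsReport(
        total_templates=total,
        observations=total - procedures,
        procedures=procedures,
        generic_mapped=generic_mapped,
        specific_terms=specific,
        generic_elements=n_elements,
        core_generic_terms=fam_counts[Family.CORE_GENERIC],
        staging_grading_classification_terms=fam_counts[
            Family.STAGING_GRADING_CLASSIFICATION
        ],
        marker_terms=fam_counts[Family.MARKER],
        organs=len(organs),
        coverage_percent=coverage,
        skipped=tuple(skipped),
    )


def snomed_coverage(concepts: Iterable[ConceptRef]) -> float:
    """Percentage of distinct concepts carrying a SNOMED code, to one decimal.

    Approximate mappings count as mapped. Exact duplicates are de-duplicated
    first; a code reused under a different designation (an alias row such as
    a morphologic abnormality listed both as target and qualifier) counts as
    its own entry, matching a row-wise hand count of the tables.
    """
    from .ontology import Namespace

    unique = {(c.namespace, c.code, c.designation.casefold()) for c in concepts}
    if not unique:
        raise CoverageUndefinedError("coverage of an empty concept collection is undefined")
    coded = sum(1 for ns, _, _ in unique if ns is Namespace.SNOMED)
    return round(100.0 * coded / len(unique), 1)
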