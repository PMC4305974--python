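"""Assembly of the packaged reference model into a ready-to-use session.

Builds the default ontology graph from the packaged target/property/qualifier
tables, installs the permissible-value role roots, wires the axis annotations
as IS-A links to local axis-root concepts (which makes the "descendants
included" rule executable without a full SNOMED CT release), registers the
profile's organs and problem organizers, and loads the equivalence table and
the default composition profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

from .decomposition import EquivalenceTable, NameGrammar
from .fixtures import CompositionProfile, profile_from_dict
from .io_formats import _slug, load_concept_table, load_equivalence_table
from .ontology import (
    Axis,
    ConceptRef,
    OntologyGraph,
    RelationshipType,
    local_concept,
)

#: Observation-method qualifiers (context element, not lesion attributes).
OBSERVATION_METHODS = (
    "ObservedByMicroscopicInvestigation",
    "ObservedByMacroscopicInvestigation",
)

#: Seed tokens of the open "specialAttributes" enumeration.
SPECIAL_ATTRIBUTES = ("Nearest", "Biggest", "Most", "Least", "Smallest", "Largest")

#: Element-name tokens that imply a special-attribute qualifier.
SPECIAL_ATTRIBUTE_TOKENS = {
    "largest": "Largest",
    "greatest": "Largest",
    "smallest": "Smallest",
    "nearest": "Nearest",
    "closest": "Nearest",
    "biggest": "Biggest",
    "most": "Most",
    "least": "Least",
}

#: Anatomy backbone: (part, whole) PART-OF pairs among the packaged targets.
_PART_OF = (
    ("Nucleolus", "Nucleus"),
    ("Mitotic nucleus", "Nucleus"),
    ("Nucleus", "Cell"),
    ("Cell", "Tissue"),
    ("Tissue", "Organ"),
    ("Margin", "Specimen"),
)


def load_default_profile(path: str | Path | None = None) -> CompositionProfile:
    if path is None:
        text = (files("pathterm.data") / "default_profile.json").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    return profile_from_dict(json.loads(text))


def build_graph(profile: CompositionProfile | None = None) -> OntologyGraph:
    """The default ontology: packaged tables, axis roots, methods, special
    attributes, plus the profile's organs and problem organizers."""
    graph = OntologyGraph()

    axis_roots: dict[Axis, ConceptRef] = {}
    for axis in Axis:
        root = local_concept(f"axis-{_slug(axis.value)}", f"{axis.value} (axis)", axis)
        graph.add_concept(root)
        axis_roots[axis] = root

    def load(table: str, role: str) -> list[ConceptRef]:
        rows = []
        for concept in load_concept_table(table):
            stored = graph.add_concept(concept)
            if concept.axis is not None:
                graph.add_relation(stored, RelationshipType.IS_A, axis_roots[concept.axis])
            rows.append(stored)
        graph.role_roots.setdefault(role, set()).update(c.key for c in rows)
        return rows

    load("targets.tsv", "target")
    load("properties.tsv", "property")
    qualifier_roots = load("qualifiers.tsv", "qualifier")

    special_root = graph.by_designation("specialAttributes")
    for token in SPECIAL_ATTRIBUTES:
        c = graph.add_concept(local_concept(_slug(token.lower()), token))
        graph.add_relation(c, RelationshipType.IS_A, special_root)

    method_root = graph.add_concept(local_concept("observationMethod"))
    graph.role_roots["method"] = {method_root.key}
    for name in OBSERVATION_METHODS:
        c = graph.add_concept(local_concept(name))
        graph.add_relation(c, RelationshipType.IS_A, method_root)

    graph.role_roots["locator"] = {axis_roots[Axis.BODY_STRUCTURE].key}
    problem_root = graph.add_concept(local_concept("pathological-problem", "pathological problem"))
    graph.role_roots["problem"] = {problem_root.key}

    for part, whole in _PART_OF:
        graph.add_relation(
            graph.by_designation(part), RelationshipType.PART_OF, graph.by_designation(whole)
        )

    # qualifiers refine the generic observation as a whole
    observation = graph.add_concept(local_concept("GenericApObservation", "generic AP observation"))
    for root in qualifier_roots + [method_root]:
        graph.add_relation(root, RelationshipType.IS_QUALIFIER_OF, observation)

    if profile is not None:
        body = axis_roots[Axis.BODY_STRUCTURE]
        for organ in profile.organs:
            c = graph.add_concept(local_concept(_slug(organ.lower()), organ, Axis.BODY_STRUCTURE))
            graph.add_relation(c, RelationshipType.IS_A, body)
        for _token, designation in profile.problems:
            c = graph.add_concept(local_concept(_slug(designation), designation))
            graph.add_relation(c, RelationshipType.IS_A, problem_root)

    return graph


def wire_recipes(graph: OntologyGraph, eq: EquivalenceTable) -> None:
    """Record each recipe's property HAS-TARGET link in the graph."""
    for row in eq.rows:
        prop = graph.by_designation(row.recipe.property)
        target = graph.by_designation(row.recipe.target)
        graph.add_relation(prop, RelationshipType.HAS_TARGET, target)


def build_grammar(profile: CompositionProfile) -> NameGrammar:
    return NameGrammar(
        delimiter="-",
        organ_lexicon=frozenset(o.casefold() for o in profile.organs),
        problem_lexicon={t.casefold(): d for t, d in profile.problems},
        special_attributes=dict(SPECIAL_ATTRIBUTE_TOKENS),
    )


@dataclass
class Session:
    """Everything needed to compose, decompose and tally in one place."""

    graph: OntologyGraph
    equivalence: EquivalenceTable
    grammar: NameGrammar
    profile: CompositionProfile


def default_session(profile_path: str | Path | None = None) -> Session:
    profile = load_default_profile(profile_path)
    graph = build_graph(profile)
    eq = load_equivalence_table()
    wire_recipes(graph, eq)
    return Session(graph=graph, equivalence=eq, grammar=build_grammar(profile), profile=profile)
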