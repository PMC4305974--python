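"""Concept graph for the generic anatomic-pathology reference terminology.

The reference model organises concepts (SNOMED CT codes plus local tokens)
into a typed directed graph with exactly four relationship types:

* ``IS_A``       — generic specialisation (acyclic),
* ``PART_OF``    — partitive anatomy (acyclic),
* ``HAS_TARGET`` — links an observation property to the entity it is about,
* ``IS_QUALIFIER_OF`` — links a qualifier to what it refines.

``IS-TARGET-OF`` is the inverse reading of ``HAS_TARGET`` and is exposed only
as a query (:meth:`OntologyGraph.is_target_of`), never stored.

Value-set membership follows the "descendants included" rule: a concept is a
permissible value for a role root if the root lies in the reflexive-transitive
``IS_A`` closure of the concept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import networkx as nx

from .errors import CycleError, MissingConceptError


class Namespace(str, Enum):
    SNOMED = "snomed"
    LOCAL = "local"


class Axis(str, Enum):
    """Top-level SNOMED CT hierarchy of a concept."""

    QUALIFIER_VALUE = "qualifier value"
    ATTRIBUTE = "attribute"
    MORPHOLOGIC_ABNORMALITY = "morphologic abnormality"
    BODY_STRUCTURE = "body structure"
    CELL_STRUCTURE = "cell structure"
    SPECIMEN = "specimen"
    DISORDER = "disorder"
    PROCEDURE = "procedure"
    OBSERVABLE_ENTITY = "observable entity"


class RelationshipType(str, Enum):
    IS_A = "IS-A"
    PART_OF = "PART-OF"
    HAS_TARGET = "HAS-TARGET"
    IS_QUALIFIER_OF = "IS-QUALIFIER-OF"


#: Relationship subgraphs that must stay acyclic.
ACYCLIC_TYPES = frozenset({RelationshipType.IS_A, RelationshipType.PART_OF})

ConceptKey = tuple[str, str]  # (namespace value, code)


@dataclass(frozen=True)
class ConceptRef:
    """A coded concept: a SNOMED CT code or a local (artifact-scoped) token.

    Identity (equality/hash) is by ``(namespace, code)`` only, so the same
    code carrying alternative designations compares equal. ``approximate``
    marks mappings the source tables print with reservations; such codes
    still count as mapped for coverage purposes.
    """

    code: str
    namespace: Namespace = Namespace.SNOMED
    designation: str = field(default="", compare=False)
    axis: Axis | None = field(default=None, compare=False)
    approximate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("concept code must be nonempty")
        if self.namespace is Namespace.SNOMED and not self.code.isdigit():
            raise ValueError(f"SNOMED code must be all digits: {self.code!r}")
        if not self.designation:
            raise ValueError(f"concept {self.code!r} needs a designation")
        if any(ch.isspace() for ch in self.code):
            raise ValueError(f"concept code may not contain whitespace: {self.code!r}")

    @property
    def key(self) -> ConceptKey:
        return (self.namespace.value, self.code)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.code}|{self.designation}|"


def local_concept(
    token: str, designation: str | None = None, axis: Axis | None = None
) -> ConceptRef:
    """Convenience constructor for a local (non-SNOMED) concept.

    ``token`` must be whitespace-free; the designation defaults to the token.
    """
    return ConceptRef(
        code=token, namespace=Namespace.LOCAL, designation=designation or token, axis=axis
    )


class OntologyGraph:
    """Mutable concept store with typed, directed, acyclicity-checked edges.

    Edges run child -> parent (e.g. ``Nucleus IS_A cell-structure-root``).
    ``role_roots`` holds named permissible-value root sets ("target",
    "property", "qualifier", "method", "locator", "problem") installed by the
    table loaders; the expression composer validates against them.
    """

    def __init__(self) -> None:
        self._concepts: dict[ConceptKey, ConceptRef] = {}
        self._designations: dict[str, ConceptKey] = {}
        self._graphs: dict[RelationshipType, nx.DiGraph] = {
            t: nx.DiGraph() for t in RelationshipType
        }
        self.role_roots: dict[str, set[ConceptKey]] = {}

    # -- concept registry ---------------------------------------------------

    def __contains__(self, concept: ConceptRef) -> bool:
        return concept.key in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def concepts(self) -> Iterator[ConceptRef]:
        return iter(self._concepts.values())

    def add_concept(self, concept: ConceptRef) -> ConceptRef:
        """Register a concept; idempotent on the ``(namespace, code)`` key.

        Re-registering an existing key with a different designation keeps the
        stored concept and records the new designation as an alias (the
        packaged tables legitimately reuse one SNOMED code under two names,
        e.g. a morphologic abnormality serving both as a target and as the
        ``abnormalStructure`` qualifier).
        """
        existing = self._concepts.get(concept.key)
        if existing is None:
            self._concepts[concept.key] = concept
            existing = concept
        self._designations.setdefault(concept.designation.casefold(), concept.key)
        return existing

    def get(self, code: str, namespace: Namespace = Namespace.SNOMED) -> ConceptRef:
        try:
            return self._concepts[(namespace.value, code)]
        except KeyError:
            raise MissingConceptError(f"unknown concept {namespace.value}:{code}") from None

    def by_designation(self, designation: str) -> ConceptRef:
        """Look a concept up by (case-insensitive) designation or alias."""
        key = self._designations.get(designation.casefold())
        if key is None:
            raise MissingConceptError(f"no concept designated {designation!r}")
        return self._concepts[key]

    def _require(self, concept: ConceptRef) -> ConceptKey:
        if concept.key not in self._concepts:
            raise MissingConceptError(
                f"concept {concept.designation!r} ({concept.namespace.value}:{concept.code}) "
                "is not registered"
            )
        return concept.key

    # -- edges --------------------------------------------------------------

    def add_relation(
        self, child: ConceptRef, type: RelationshipType, parent: ConceptRef
    ) -> "OntologyGraph":
        """Add ``child -[type]-> parent``; idempotent for duplicate edges.

        For ``IS_A`` and ``PART_OF`` the edge is refused with
        :class:`CycleError` (naming the offending path) if it would close a
        cycle.
        """
        ckey = self._require(child)
        pkey = self._require(parent)
        g = self._graphs[type]
        if g.has_edge(ckey, pkey):
            return self
        if type in ACYCLIC_TYPES:
            if ckey == pkey:
                raise CycleError([child.designation, parent.designation])
            if pkey in g and ckey in g and nx.has_path(g, pkey, ckey):
                path = nx.shortest_path(g, pkey, ckey)
                names = [self._concepts[k].designation for k in path]
                raise CycleError([child.designation] + names)
        g.add_edge(ckey, pkey)
        return self

    def has_relation(
        self, child: ConceptRef, type: RelationshipType, parent: ConceptRef
    ) -> bool:
        return self._graphs[type].has_edge(child.key, parent.key)

    def edges(self) -> Iterator[tuple[ConceptRef, RelationshipType, ConceptRef]]:
        for t, g in self._graphs.items():
            for c, p in g.edges():
                yield self._concepts[c], t, self._concepts[p]

    # -- queries ------------------------------------------------------------

    def closure(self, concept: ConceptRef, type: RelationshipType) -> set[ConceptRef]:
        """Reflexive-transitive closure of ``concept`` along ``type`` edges.

        Follows edges child -> parent, so for ``IS_A`` this is the set of the
        concept and all its ancestors.
        """
        key = self._require(concept)
        g = self._graphs[type]
        keys = {key}
        if key in g:
            keys |= nx.descendants(g, key)  # descendants in edge direction = ancestors
        return {self._concepts[k] for k in keys}

    def descendants(self, concept: ConceptRef, type: RelationshipType) -> set[ConceptRef]:
        """Concept plus everything below it ("their descendants included")."""
        key = self._require(concept)
        g = self._graphs[type]
        keys = {key}
        if key in g:
            keys |= nx.ancestors(g, key)
        return {self._concepts[k] for k in keys}

    def is_permissible(self, candidate: ConceptRef, role_root: ConceptRef) -> bool:
        """True iff ``candidate`` is ``role_root`` or one of its descendants."""
        self._require(role_root)
        return role_root in self.closure(candidate, RelationshipType.IS_A)

    def permissible_for_role(self, candidate: ConceptRef, role: str) -> bool:
        """Check ``candidate`` against any root in the named role-root set."""
        roots = self.role_roots.get(role, set())
        anc = {c.key for c in self.closure(candidate, RelationshipType.IS_A)}
        return bool(anc & roots)

    def is_target_of(self, target: ConceptRef) -> set[ConceptRef]:
        """Inverse view of ``HAS_TARGET``: properties observing ``target``."""
        key = self._require(target)
        g = self._graphs[RelationshipType.HAS_TARGET]
        if key not in g:
            return set()
        return {self._concepts[k] for k in g.predecessors(key)}

    def check_invariants(self) -> None:
        """Raise if an acyclic subgraph acquired a cycle or an edge endpoint
        is unregistered (defensive; mutation paths already prevent both)."""
        for t in ACYCLIC_TYPES:
            if not nx.is_directed_acyclic_graph(self._graphs[t]):
                cyc = nx.find_cycle(self._graphs[t])
                raise CycleError([self._concepts[c].designation for c, _ in cyc])
        for g in self._graphs.values():
            for node in g.nodes():
                if node not in self._concepts:
                    raise MissingConceptError(f"dangling edge endpoint {node}")


def register_all(graph: OntologyGraph, concepts: Iterable[ConceptRef]) -> None:
    for c in concepts:
        graph.add_concept(c)
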