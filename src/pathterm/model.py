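"""Postcoordinated generic observation expressions.

An anatomic-pathology observation is modelled as a context (locator organ,
pathological-problem organizer, observation method) plus three basic
elements: exactly one *target* (the entity observed: specimen, lesion,
nucleus, margin ...), exactly one *property* (the attribute measured or
judged: diameter, grade, colour ...) and any number of *qualifiers*
(laterality, invasiveness, "largest" ...), optionally closed by a coded or
quantitative value.

Expressions are canonical: qualifiers are de-duplicated and sorted by
``(namespace, code)``, so equality is order-insensitive. Validation is
aggregated — :func:`compose` reports every role violation at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import (
    ExpressionValidationError,
    GraphMismatchError,
    PathtermError,
    RoleConstraintError,
)
from .ontology import ConceptRef, Namespace, OntologyGraph, RelationshipType

#: Reserved prefix for local concepts in compositional-grammar renderings.
SCG_LOCAL_PREFIX = "PL-"


@dataclass(frozen=True)
class Target:
    concept: ConceptRef


@dataclass(frozen=True)
class Property:
    concept: ConceptRef


@dataclass(frozen=True)
class Qualifier:
    concept: ConceptRef


@dataclass(frozen=True)
class Context:
    """Where/about-what/how the observation was made.

    All parts are optional at expression level: a generic term exists
    context-free, and context is bound at document level when needed.
    """

    locator: ConceptRef | None = None
    problem: ConceptRef | None = None
    method: Qualifier | None = None

    @property
    def is_empty(self) -> bool:
        return self.locator is None and self.problem is None and self.method is None


@dataclass(frozen=True)
class ObservationValue:
    """Either a coded value or a quantity with a UCUM-style unit token."""

    coded: ConceptRef | None = None
    magnitude: float | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        has_code = self.coded is not None
        has_qty = self.magnitude is not None
        if has_code == has_qty:
            raise ValueError("exactly one of coded / quantity must be populated")
        if has_qty:
            import math

            if not math.isfinite(self.magnitude):  # type: ignore[arg-type]
                raise ValueError("quantity magnitude must be finite")
            if not self.unit:
                raise ValueError("quantity requires a nonempty unit")
        elif self.unit is not None:
            raise ValueError("unit is only meaningful with a quantity")


@dataclass(frozen=True)
class GenericObservation:
    """A validated, canonical postcoordinated observation expression."""

    context: Context
    target: Target
    property: Property
    qualifiers: tuple[Qualifier, ...]
    value: ObservationValue | None = None
    graph: OntologyGraph | None = field(default=None, compare=False, repr=False)

    def all_qualifiers(self) -> tuple[Qualifier, ...]:
        """General qualifiers plus the observation-method qualifier, if any."""
        if self.context.method is None:
            return self.qualifiers
        return tuple(
            sorted(
                set(self.qualifiers) | {self.context.method},
                key=lambda q: (q.concept.namespace.value, q.concept.code),
            )
        )


def _canonical_qualifiers(qualifiers: Iterable[Qualifier]) -> tuple[Qualifier, ...]:
    return tuple(
        sorted(set(qualifiers), key=lambda q: (q.concept.namespace.value, q.concept.code))
    )


def compose(
    graph: OntologyGraph,
    target: Target,
    property: Property,
    qualifiers: Sequence[Qualifier] = (),
    context: Context | None = None,
    value: ObservationValue | None = None,
) -> GenericObservation:
    """Validate all components against ``graph`` and build a canonical
    expression.

    Role checks use the graph's installed permissible-value root sets
    ("descendants included"): the target under a target root, the property
    under a property root, each qualifier under a qualifier or method root,
    the locator under a body-structure root, the problem under the
    pathological-problem root. Violations are aggregated into a single
    :class:`ExpressionValidationError`.
    """
    context = context or Context()
    errors: list[PathtermError] = []

    def check(role: str, concept: ConceptRef, roles: tuple[str, ...]) -> None:
        try:
            if not any(graph.permissible_for_role(concept, r) for r in roles):
                errors.append(RoleConstraintError(role, concept.designation))
        except PathtermError as exc:
            errors.append(exc)

    check("target", target.concept, ("target",))
    check("property", property.concept, ("property",))
    for q in qualifiers:
        check("qualifier", q.concept, ("qualifier", "method"))
    if context.locator is not None:
        check("locator", context.locator, ("locator",))
    if context.problem is not None:
        check("problem", context.problem, ("problem",))
    if context.method is not None:
        check("method", context.method.concept, ("method",))
    if value is not None and value.coded is not None and value.coded not in graph:
        # coded values may come from value sets not modelled here; only
        # require registration so closures stay answerable
        graph.add_concept(value.coded)

    if errors:
        raise ExpressionValidationError(errors)

    return GenericObservation(
        context=context,
        target=target,
        property=property,
        qualifiers=_canonical_qualifiers(qualifiers),
        value=value,
        graph=graph,
    )


def _slot_subsumes(
    graph: OntologyGraph, general: ConceptRef | None, specific: ConceptRef | None
) -> bool:
    """Absent slot in the general expression matches anything; otherwise the
    general concept must be an (improper) IS-A ancestor of the specific one."""
    if general is None:
        return True
    if specific is None:
        return False
    return general in graph.closure(specific, RelationshipType.IS_A)


def subsumes(a: GenericObservation, b: GenericObservation) -> bool:
    """True iff ``a`` is at least as general as ``b``.

    Slot-wise: b's target/property/locator/problem must each lie in the
    descendant closure of a's corresponding slot (an absent slot in ``a`` is
    most-general), and every qualifier of ``a`` must subsume some qualifier
    of ``b``. Reflexive and transitive.
    """
    if a.graph is None or b.graph is None or a.graph is not b.graph:
        raise GraphMismatchError("expressions were validated against different graphs")
    g = a.graph
    if not _slot_subsumes(g, a.target.concept, b.target.concept):
        return False
    if not _slot_subsumes(g, a.property.concept, b.property.concept):
        return False
    if not _slot_subsumes(g, a.context.locator, b.context.locator):
        return False
    if not _slot_subsumes(g, a.context.problem, b.context.problem):
        return False
    a_method = a.context.method.concept if a.context.method else None
    b_method = b.context.method.concept if b.context.method else None
    if not _slot_subsumes(g, a_method, b_method):
        return False
    for qa in a.qualifiers:
        if not any(
            _slot_subsumes(g, qa.concept, qb.concept) for qb in b.qualifiers
        ):
            return False
    return True


# -- compositional-grammar rendering ---------------------------------------
#
# Dialect (parsed back by io_formats.parse_scg):
#   expression := term [ " : " part { ", " part } ]
#   part       := term                      (the single property, always first)
#               | key " = " term            (qualifier / method / locator / problem / value)
#               | "value = #" number " |" unit "|"
#   term       := code " |" designation-lowercased "|"
# Local concepts carry the reserved "PL-" code prefix.


def _scg_term(concept: ConceptRef) -> str:
    code = concept.code if concept.namespace is Namespace.SNOMED else SCG_LOCAL_PREFIX + concept.code
    return f"{code} |{concept.designation.lower()}|"


def to_scg(expr: GenericObservation) -> str:
    """Render the expression in the package's SNOMED-compositional-grammar
    dialect; deterministic for a canonical expression."""
    parts = [_scg_term(expr.property.concept)]
    parts += [f"qualifier = {_scg_term(q.concept)}" for q in expr.qualifiers]
    if expr.context.method is not None:
        parts.append(f"method = {_scg_term(expr.context.method.concept)}")
    if expr.context.locator is not None:
        parts.append(f"locator = {_scg_term(expr.context.locator)}")
    if expr.context.problem is not None:
        parts.append(f"problem = {_scg_term(expr.context.problem)}")
    if expr.value is not None:
        if expr.value.coded is not None:
            parts.append(f"value = {_scg_term(expr.value.coded)}")
        else:
            mag = repr(expr.value.magnitude)
            parts.append(f"value = #{mag} |{expr.value.unit}|")
    return f"{_scg_term(expr.target.concept)} : " + ", ".join(parts)
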