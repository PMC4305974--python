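"""Synthetic interface-terminology registries from a composition profile.

Real checklist-driven interface registries are distributed as spreadsheets
and cannot be shipped here; this module generates a registry with the same
*composition* from a declarative profile: how many templates per family
(core-generic, staging/grading/classification, marker, specific, procedure),
which organs and problem organizers provide context, and which value set
each element carries.

Generic-family elements keep an identical value set in every context, so the
value-set-uniqueness criterion classifies them generic; specific-family
elements get a perturbed value set in at least one context, so the same
criterion separates them. The decomposer sees only names and value sets,
never generator internals, which makes the generator -> decomposer round
trip a meaningful check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .decomposition import Category, PrecoordinatedTerm
from .errors import ConfigurationError, MissingConceptError
from .ontology import OntologyGraph


@dataclass(frozen=True)
class ElementSpec:
    """One element of a family: its name, how many (organ, problem) contexts
    it is expanded over, and its value set."""

    element: str
    contexts: int
    value_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.contexts < 0:
            raise ValueError("context count must be >= 0")
        if not self.element.strip():
            raise ValueError("element name must be nonempty")


@dataclass(frozen=True)
class CompositionProfile:
    organs: tuple[str, ...]
    problems: tuple[tuple[str, str], ...]  # (name token, problem designation)
    core_generic: tuple[ElementSpec, ...] = ()
    staging_grading_classification: tuple[ElementSpec, ...] = ()
    marker: tuple[ElementSpec, ...] = ()
    procedure_observation: tuple[ElementSpec, ...] = ()
    specific: tuple[ElementSpec, ...] = ()
    procedures: tuple[str, ...] = ()
    seed: int = 0
    oid_branch: str = "2.999.1.4"
    organ_stride: int = 7

    def __post_init__(self) -> None:
        context_bearing = sum(
            s.contexts
            for fam in (
                self.core_generic,
                self.staging_grading_classification,
                self.marker,
                self.procedure_observation,
                self.specific,
            )
            for s in fam
        )
        if context_bearing > 0 and not self.organs:
            raise ValueError("organ list must be nonempty when context-bearing counts > 0")
        for s in self.specific:
            if s.contexts < 2:
                raise ValueError(
                    "specific elements need >= 2 contexts so value-set perturbation "
                    "can violate uniqueness"
                )

    @property
    def generic_families(self) -> tuple[tuple[str, tuple[ElementSpec, ...]], ...]:
        return (
            ("core_generic", self.core_generic),
            ("staging_grading_classification", self.staging_grading_classification),
            ("marker", self.marker),
            ("procedure_observation", self.procedure_observation),
        )

    @property
    def total_templates(self) -> int:
        generic = sum(s.contexts for _, fam in self.generic_families for s in fam)
        specific = sum(s.contexts for s in self.specific)
        return generic + specific + len(self.procedures)


def profile_from_dict(d: dict) -> CompositionProfile:
    fams = d.get("families", {})

    def specs(key: str) -> tuple[ElementSpec, ...]:
        return tuple(
            ElementSpec(
                element=e["element"],
                contexts=int(e["contexts"]),
                value_set=tuple(e.get("value_set", ())),
            )
            for e in fams.get(key, ())
        )

    return CompositionProfile(
        organs=tuple(d["organs"]),
        problems=tuple((p["token"], p["designation"]) for p in d["problems"]),
        core_generic=specs("core_generic"),
        staging_grading_classification=specs("staging_grading_classification"),
        marker=specs("marker"),
        procedure_observation=specs("procedure_observation"),
        specific=specs("specific"),
        procedures=tuple(fams.get("procedures", ())),
        seed=int(d.get("seed", 0)),
        oid_branch=d.get("oid_branch", "2.999.1.4"),
        organ_stride=int(d.get("organ_stride", 7)),
    )


def _check_profile_concepts(profile: CompositionProfile, graph: OntologyGraph) -> None:
    for organ in profile.organs:
        try:
            graph.by_designation(organ)
        except MissingConceptError as exc:
            raise ConfigurationError(f"profile organ {organ!r} not registered") from exc
    for _, designation in profile.problems:
        try:
            graph.by_designation(designation)
        except MissingConceptError as exc:
            raise ConfigurationError(f"profile problem {designation!r} not registered") from exc


def generate_registry(
    profile: CompositionProfile,
    graph: OntologyGraph | None = None,
    seed: int | None = None,
) -> list[PrecoordinatedTerm]:
    """Emit exactly the profiled number of templates per family.

    Context-bearing names follow the "Organ-Problem-Element" grammar; the
    (organ, problem) contexts of an element are assigned deterministically by
    striding through the organ list (stride coprime to its length, so every
    element sees distinct organs and the registry as a whole covers all of
    them) while alternating problem organizers. OIDs are allocated
    sequentially under the profile's reserved branch. The random seed only
    shuffles the final row order; the composition is profile data.
    """
    if graph is not None:
        _check_profile_concepts(profile, graph)
    rng = random.Random(profile.seed if seed is None else seed)
    organs = profile.organs
    problems = profile.problems
    rows: list[PrecoordinatedTerm] = []
    next_oid = 1
    element_index = 0

    def alloc() -> str:
        nonlocal next_oid
        oid = f"{profile.oid_branch}.{next_oid}"
        next_oid += 1
        return oid

    def contexts_for(spec: ElementSpec) -> list[tuple[str, tuple[str, str]]]:
        base = element_index * profile.organ_stride
        return [
            (organs[(base + j) % len(organs)], problems[j % len(problems)])
            for j in range(spec.contexts)
        ]

    for _, family in profile.generic_families:
        for spec in family:
            for organ, (ptoken, _pdesig) in contexts_for(spec):
                rows.append(
                    PrecoordinatedTerm(
                        oid=alloc(),
                        name=f"{organ}-{ptoken}-{spec.element}",
                        organ=organ,
                        problem=ptoken,
                        category=Category.OBSERVATION,
                        value_set=spec.value_set,
                    )
                )
            element_index += 1

    for spec in profile.specific:
        for j, (organ, (ptoken, _pdesig)) in enumerate(contexts_for(spec)):
            value_set = spec.value_set
            if j == 0:
                # minimal violation of the uniqueness criterion: one context
                # carries one extra member
                value_set = value_set + (f"{spec.element} ({organ} variant)",)
            rows.append(
                PrecoordinatedTerm(
                    oid=alloc(),
                    name=f"{organ}-{ptoken}-{spec.element}",
                    organ=organ,
                    problem=ptoken,
                    category=Category.OBSERVATION,
                    value_set=value_set,
                )
            )
        element_index += 1

    for name in profile.procedures:
        rows.append(
            PrecoordinatedTerm(
                oid=alloc(), name=name, category=Category.PROCEDURE, value_set=()
            )
        )

    rng.shuffle(rows)
    return rows


def random_observation(graph: OntologyGraph, rng: random.Random):
    """A random valid expression over the default ontology (test helper).

    Draws target/property from the installed role roots, zero to three
    qualifiers, optional context and value.
    """
    from .model import Context, ObservationValue, Property, Qualifier, Target, compose
    from .ontology import RelationshipType

    def pool(role: str):
        keys = sorted(graph.role_roots.get(role, ()))
        out = []
        for ns, code in keys:
            root = graph.get(code, _ns(ns))
            out.extend(sorted(graph.descendants(root, RelationshipType.IS_A),
                              key=lambda c: c.key))
        return out

    def _ns(value: str):
        from .ontology import Namespace

        return Namespace(value)

    targets = pool("target")
    properties = pool("property")
    qualifiers = pool("qualifier") + pool("method")
    locators = pool("locator")
    problems = pool("problem")

    ctx = Context(
        locator=rng.choice(locators) if locators and rng.random() < 0.5 else None,
        problem=rng.choice(problems) if problems and rng.random() < 0.5 else None,
        method=Qualifier(rng.choice(pool("method"))) if rng.random() < 0.5 else None,
    )
    value = None
    r = rng.random()
    if r < 0.3:
        value = ObservationValue(magnitude=round(rng.uniform(0.1, 50.0), 2), unit="mm")
    return compose(
        graph,
        target=Target(rng.choice(targets)),
        property=Property(rng.choice(properties)),
        qualifiers=[Qualifier(rng.choice(qualifiers)) for _ in range(rng.randint(0, 3))],
        context=ctx,
        value=value,
    )
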