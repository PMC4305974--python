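"""Expression composition, canonicalization, subsumption, SCG rendering."""

import random

import pytest

from pathterm.errors import ExpressionValidationError, GraphMismatchError
from pathterm.fixtures import random_observation
from pathterm.model import (
    Context,
    ObservationValue,
    Property,
    Qualifier,
    Target,
    compose,
    subsumes,
    to_scg,
)
from pathterm.ontology import RelationshipType


def _c(graph, designation):
    return graph.by_designation(designation)


class TestCompose:
    def test_breast_worked_example(self, graph):
        expr = compose(
            graph,
            target=Target(_c(graph, "Lesion")),
            property=Property(_c(graph, "Diameter")),
            qualifiers=[Qualifier(_c(graph, "Largest"))],
            context=Context(
                locator=_c(graph, "Breast"),
                problem=_c(graph, "non-invasive tumor"),
                method=Qualifier(_c(graph, "ObservedByMicroscopicInvestigation")),
            ),
        )
        assert expr.target.concept.code == "49755003"
        assert expr.property.concept.code == "81827009"
        names = {q.concept.designation for q in expr.all_qualifiers()}
        assert names == {"Largest", "ObservedByMicroscopicInvestigation"}

    def test_specimen_weight_without_context(self, graph):
        expr = compose(
            graph,
            target=Target(_c(graph, "Specimen")),
            property=Property(_c(graph, "Weight")),
        )
        assert expr.context.is_empty
        assert expr.qualifiers == ()

    def test_role_disjointness_rejected(self, graph):
        with pytest.raises(ExpressionValidationError) as exc:
            compose(
                graph,
                target=Target(_c(graph, "Specimen")),
                property=Property(_c(graph, "Lesion")),  # a target, not a property
            )
        assert any(
            getattr(e, "role", None) == "property" for e in exc.value.errors
        )

    def test_errors_are_aggregated(self, graph):
        with pytest.raises(ExpressionValidationError) as exc:
            compose(
                graph,
                target=Target(_c(graph, "Weight")),  # property in target role
                property=Property(_c(graph, "Lesion")),  # target in property role
            )
        assert len(exc.value.errors) == 2

    def test_qualifiers_canonical_and_deduplicated(self, graph):
        largest = Qualifier(_c(graph, "Largest"))
        lat = Qualifier(_c(graph, "Laterality"))
        a = compose(graph, Target(_c(graph, "Lesion")), Property(_c(graph, "Diameter")),
                    qualifiers=[largest, lat, largest])
        b = compose(graph, Target(_c(graph, "Lesion")), Property(_c(graph, "Diameter")),
                    qualifiers=[lat, largest])
        assert a == b
        assert len(a.qualifiers) == 2

    def test_observation_value_exclusivity(self):
        with pytest.raises(ValueError):
            ObservationValue()
        with pytest.raises(ValueError):
            ObservationValue(magnitude=3.0)  # unit missing
        with pytest.raises(ValueError):
            ObservationValue(magnitude=float("inf"), unit="mm")


class TestSubsumes:
    def test_reflexive_on_random_expressions(self, graph, rng):
        for _ in range(30):
            x = random_observation(graph, rng)
            assert subsumes(x, x)

    def test_fewer_qualifiers_is_more_general(self, graph):
        base = dict(target=Target(_c(graph, "Lesion")), property=Property(_c(graph, "Diameter")))
        a = compose(graph, **base)
        b = compose(graph, **base, qualifiers=[Qualifier(_c(graph, "Largest"))])
        assert subsumes(a, b)
        assert not subsumes(b, a)

    def test_absent_context_is_most_general(self, graph):
        base = dict(target=Target(_c(graph, "Lesion")), property=Property(_c(graph, "Diameter")))
        a = compose(graph, **base)
        b = compose(graph, **base, context=Context(locator=_c(graph, "Breast")))
        assert subsumes(a, b) and not subsumes(b, a)

    def test_graph_mismatch_rejected(self, graph):
        from pathterm.defaults import build_graph

        other = build_graph()
        a = compose(graph, Target(_c(graph, "Specimen")), Property(_c(graph, "Weight")))
        b = compose(other, Target(_c(other, "Specimen")), Property(_c(other, "Weight")))
        with pytest.raises(GraphMismatchError):
            subsumes(a, b)

    def _oracle(self, graph, a, b):
        """Slot-wise closure check, written independently of subsumes()."""

        def anc(c):
            return graph.closure(c, RelationshipType.IS_A)

        def slot_ok(ga, gb):
            if ga is None:
                return True
            return gb is not None and ga in anc(gb)

        am = a.context.method.concept if a.context.method else None
        bm = b.context.method.concept if b.context.method else None
        checks = [
            a.target.concept in anc(b.target.concept),
            a.property.concept in anc(b.property.concept),
            slot_ok(a.context.locator, b.context.locator),
            slot_ok(a.context.problem, b.context.problem),
            slot_ok(am, bm),
        ]
        for qa in a.qualifiers:
            checks.append(any(qa.concept in anc(qb.concept) for qb in b.qualifiers))
        return all(checks)

    def test_matches_slotwise_oracle_on_random_pairs(self, graph, rng):
        exprs = [random_observation(graph, rng) for _ in range(25)]
        for a in exprs:
            for b in exprs:
                assert subsumes(a, b) == self._oracle(graph, a, b)

    def test_transitive_on_random_triples(self, graph, rng):
        exprs = [random_observation(graph, rng) for _ in range(15)]
        for a in exprs:
            for b in exprs:
                for c in exprs:
                    if subsumes(a, b) and subsumes(b, c):
                        assert subsumes(a, c)


class TestScg:
    def test_specimen_weight_rendering(self, graph):
        expr = compose(graph, Target(_c(graph, "Specimen")), Property(_c(graph, "Weight")))
        assert to_scg(expr) == "123038009 |specimen| : 272102008 |weight|"

    def test_worked_example_contains_codes(self, graph):
        expr = compose(
            graph,
            Target(_c(graph, "Lesion")),
            Property(_c(graph, "Diameter")),
            qualifiers=[Qualifier(_c(graph, "Largest"))],
            context=Context(locator=_c(graph, "Breast")),
        )
        s = to_scg(expr)
        assert "49755003" in s and "81827009" in s

    def test_stable_across_runs(self, graph):
        rng1, rng2 = random.Random(5), random.Random(5)
        s1 = to_scg(random_observation(graph, rng1))
        s2 = to_scg(random_observation(graph, rng2))
        assert s1 == s2
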