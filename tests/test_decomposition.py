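"""Name parsing, equivalence matching, genericity, stats, coverage."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathterm.decomposition import (
    Category,
    PrecoordinatedTerm,
    Verdict,
    classify_genericity,
    decompose_term,
    parse_name,
    registry_stats,
    snomed_coverage,
)
from pathterm.errors import CoverageUndefinedError, NameParseError, NotFoundError
from pathterm.io_formats import load_concept_table
from pathterm.ontology import ConceptRef, Namespace, local_concept


def _term(name, oid="2.999.1.4.9999", category=Category.OBSERVATION, value_set=()):
    return PrecoordinatedTerm(
        oid=oid, name=name, category=category, value_set=tuple(value_set)
    )


class TestParseName:
    @pytest.mark.parametrize(
        "name, organ, problem, element",
        [
            (
                "Breast-In situ neoplasm-Lesion size, largest dimension",
                "Breast", "In situ neoplasm", "Lesion size, largest dimension",
            ),
            ("Specimen weight", None, None, "Specimen weight"),
            # delimiter inside the element survives because PD is no organ
            ("Lung-Invasive neoplasm-PD-L1 expression", "Lung", "Invasive neoplasm",
             "PD-L1 expression"),
            # organ without recognised problem: one context segment only
            ("Breast-Margins involvement", "Breast", None, "Margins involvement"),
        ],
    )
    def test_grammar(self, session, name, organ, problem, element):
        parsed = parse_name(name, session.grammar)
        assert (parsed.organ, parsed.problem, parsed.element) == (organ, problem, element)

    @pytest.mark.parametrize("bad", ["", "   ", "-", "--"])
    def test_degenerate_names_rejected(self, session, bad):
        with pytest.raises(NameParseError):
            parse_name(bad, session.grammar)

    @settings(derandomize=True, max_examples=200)
    @given(
        organ_idx=st.integers(min_value=0, max_value=19),
        problem_idx=st.integers(min_value=0, max_value=1),
        element=st.text(
            alphabet="abcdefghij KLMNO,.()", min_size=1, max_size=30
        ).filter(lambda s: s.strip()),
    )
    def test_context_bearing_names_round_trip(self, session, organ_idx, problem_idx, element):
        """Any delimiter-free element survives the Organ-Problem-Element
        grammar unchanged."""
        organ = session.profile.organs[organ_idx]
        token = session.profile.problems[problem_idx][0]
        parsed = parse_name(f"{organ}-{token}-{element}", session.grammar)
        assert parsed.organ == organ
        assert parsed.problem == token
        assert parsed.element == element.strip()


class TestDecomposeTerm:
    def test_breast_worked_example(self, session):
        term = _term("Breast-In situ neoplasm-Lesion size, largest dimension",
                     oid="1.3.6.1.4.1.49376.1.8.1.4.442")
        r = decompose_term(term, session.equivalence, session.graph, session.grammar)
        assert r.verdict is Verdict.GENERIC
        assert r.matched_generic_element == "Diameter"
        expr = r.expression
        assert expr.target.concept.designation == "Lesion"
        assert expr.property.concept.designation == "Diameter"
        assert {q.concept.designation for q in expr.all_qualifiers()} == {
            "ObservedByMicroscopicInvestigation", "Largest",
        }
        assert expr.context.locator.designation == "Breast"
        assert expr.context.problem.designation == "non-invasive tumor"

    def test_specimen_weight(self, session):
        term = _term("Specimen weight", oid="1.3.6.1.4.1.19376.1.8.1.4.160")
        r = decompose_term(term, session.equivalence, session.graph, session.grammar)
        assert r.verdict is Verdict.GENERIC
        assert r.matched_generic_element == "Weight"
        assert r.expression.target.concept.designation == "Specimen"
        assert r.expression.property.concept.designation == "Weight"

    def test_unmatched_element_is_specific(self, session):
        term = _term("Liver-Invasive neoplasm-ZZZ unknown feature")
        r = decompose_term(term, session.equivalence, session.graph, session.grammar)
        assert r.verdict is Verdict.SPECIFIC
        assert r.expression is None
        assert "ZZZ unknown feature" in r.unmatched_reason

    def test_procedure_category_short_circuits(self, session):
        term = _term("Specimen photography", category=Category.PROCEDURE)
        r = decompose_term(term, session.equivalence, session.graph, session.grammar)
        assert r.verdict is Verdict.PROCEDURE

    def test_longest_pattern_wins(self, session):
        # "Macroscopic type" contains the Class pattern token "type" but the
        # two-token exact pattern must take precedence
        r = decompose_term(_term("Macroscopic type"), session.equivalence,
                           session.graph, session.grammar)
        assert r.matched_row == "Growth pattern"

    def test_staging_identity_is_element_name(self, session):
        r = decompose_term(_term("Colon-Invasive neoplasm-pT"), session.equivalence,
                           session.graph, session.grammar)
        assert r.verdict is Verdict.GENERIC
        assert r.matched_row == "Stage"
        assert r.matched_generic_element == "pT"


class TestClassifyGenericity:
    def _registry(self, value_sets):
        organs = ["Breast", "Lung", "Colon"]
        return [
            _term(f"{organs[i]}-Invasive neoplasm-Mystery feature",
                  oid=f"2.999.1.4.{i+1}", value_set=vs)
            for i, vs in enumerate(value_sets)
        ]

    def test_identical_value_sets_generic(self, session):
        reg = self._registry([("a", "b")] * 3)
        assert classify_genericity("Mystery feature", reg, session.grammar) is Verdict.GENERIC

    def test_differing_value_sets_specific(self, session):
        reg = self._registry([("a", "b"), ("a", "b"), ("a", "b", "c")])
        assert classify_genericity("Mystery feature", reg, session.grammar) is Verdict.SPECIFIC

    def test_single_occurrence_policy(self, session):
        reg = self._registry([("a",)])
        assert classify_genericity("Mystery feature", reg, session.grammar) is Verdict.GENERIC
        assert classify_genericity(
            "Mystery feature", reg, session.grammar, single_occurrence_generic=False
        ) is Verdict.SPECIFIC

    def test_absent_element_not_found(self, session):
        with pytest.raises(NotFoundError):
            classify_genericity("Nope", self._registry([("a",)]), session.grammar)

    def test_permutation_invariance(self, session):
        rng = random.Random(3)
        reg = self._registry([("a", "b"), ("b", "a"), ("a", "b")])
        for _ in range(5):
            rng.shuffle(reg)
            assert classify_genericity("Mystery feature", reg, session.grammar) is Verdict.GENERIC


class TestRegistryStats:
    def test_empty_registry_all_zero(self, session):
        report = registry_stats([], session.equivalence, session.graph, session.grammar)
        assert report.total_templates == 0
        assert report.generic_elements == 0
        assert report.coverage_percent == 0.0

    def test_counts_equal_bruteforce_recount(self, session, rng):
        from pathterm.fixtures import CompositionProfile, ElementSpec, generate_registry

        profile = CompositionProfile(
            organs=tuple(session.profile.organs[:5]),
            problems=session.profile.problems,
            core_generic=(ElementSpec("Specimen weight", 4),),
            staging_grading_classification=(ElementSpec("pT", 3, ("pT1", "pT2")),),
            marker=(ElementSpec("HER2 expression", 2, ("Positive", "Negative")),),
            specific=(ElementSpec("Odd local feature", 2, ("Present",)),),
            procedures=("Specimen photography",),
        )
        registry = generate_registry(profile, session.graph)
        report = registry_stats(registry, session.equivalence, session.graph, session.grammar)

        # independent recount straight from decompose_term outputs
        verdicts = [
            decompose_term(t, session.equivalence, session.graph, session.grammar).verdict
            for t in registry
        ]
        assert report.total_templates == len(registry) == 12
        assert report.procedures == verdicts.count(Verdict.PROCEDURE)
        assert report.specific_terms == verdicts.count(Verdict.SPECIFIC)
        assert report.generic_mapped == verdicts.count(Verdict.GENERIC)
        assert report.observations == report.generic_mapped + report.specific_terms
        assert report.generic_elements == 3

    def test_conservation_on_default_registry(self, session, default_registry):
        report = registry_stats(
            default_registry, session.equivalence, session.graph, session.grammar
        )
        assert report.observations + report.procedures == report.total_templates
        assert report.generic_mapped + report.specific_terms == report.observations
        fam = (report.core_generic_terms + report.marker_terms
               + report.staging_grading_classification_terms)
        assert fam <= report.generic_elements


class TestSnomedCoverage:
    def test_all_coded(self):
        cs = [ConceptRef(code=str(i), designation=f"c{i}") for i in (1, 2, 3)]
        assert snomed_coverage(cs) == 100.0

    def test_none_coded(self):
        assert snomed_coverage([local_concept("a"), local_concept("b")]) == 0.0

    def test_empty_collection_undefined(self):
        with pytest.raises(CoverageUndefinedError):
            snomed_coverage([])

    def test_packaged_tables_row_count(self):
        concepts = []
        for table in ("targets.tsv", "properties.tsv", "qualifiers.tsv"):
            concepts.extend(load_concept_table(table))
        assert len(concepts) == 39
        assert snomed_coverage(concepts) == 94.9

    def test_duplicate_invariance(self):
        cs = [ConceptRef(code="123", designation="x"), local_concept("y")]
        assert snomed_coverage(cs) == snomed_coverage(cs * 3)
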