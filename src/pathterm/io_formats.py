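"""Readers and writers: registry TSV dialect, packaged tables, JSON/XML/SCG.

The registry dialect is a portable, delimited stand-in for spreadsheet-based
interface-terminology registries: tab-delimited UTF-8, header row required,
columns ``oid, name, organ, problem, category, value_set`` with value-set
members separated by ``|`` (commas legitimately occur inside names such as
"Lesion size, largest dimension", so they are never delimiters).

Expression serializations: canonical JSON, an HL7-template-style XML document
(validated against the shipped XSD; relationships carried as attributes
``HAS-TARGET`` / ``IS-QUALIFIER-OF``), and the compositional-grammar dialect
rendered by :func:`pathterm.model.to_scg`. All writers are deterministic
byte-for-byte for a canonical expression.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .decomposition import (
    OID_RE,
    Category,
    EquivalenceRow,
    EquivalenceTable,
    Family,
    PrecoordinatedTerm,
    Recipe,
)
from .errors import DialectError, SerializationError
from .model import (
    SCG_LOCAL_PREFIX,
    Context,
    GenericObservation,
    ObservationValue,
    Property,
    Qualifier,
    Target,
    compose,
)
from .ontology import Axis, ConceptRef, Namespace, OntologyGraph

#: HL7 OID of SNOMED CT, used as codeSystem for SNOMED-coded concepts.
SNOMED_CT_OID = "2.16.840.1.113883.6.96"
#: Reserved branch for this package's local concepts.
LOCAL_CODESYSTEM_OID = "2.999.1.1"

XML_NS = "urn:x-pathterm:observation:1"

_DATA = files("pathterm.data")


# -- registry dialect -------------------------------------------------------


@dataclass(frozen=True)
class PathlexDialect:
    delimiter: str = "\t"
    columns: tuple[str, ...] = ("oid", "name", "organ", "problem", "category", "value_set")
    value_set_sep: str = "|"
    encoding: str = "utf-8"


@dataclass(frozen=True)
class RowError:
    line: int
    oid: str
    reason: str


@dataclass
class RegistryReadResult:
    terms: list[PrecoordinatedTerm]
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)


def read_registry(
    path: str | Path, dialect: PathlexDialect = PathlexDialect()
) -> RegistryReadResult:
    """Read a registry file; malformed rows go to the error report, never
    silently dropped."""
    path = Path(path)
    result = RegistryReadResult(terms=[])
    with path.open("r", encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError(f"{path}: empty file, header row required") from None
        if tuple(h.strip() for h in header) != dialect.columns:
            raise DialectError(
                f"{path}: header {header!r} does not match dialect columns "
                f"{list(dialect.columns)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            row = list(row) + [""] * (len(dialect.columns) - len(row))
            rec = dict(zip(dialect.columns, row))
            oid = rec["oid"].strip()
            if not OID_RE.match(oid):
                result.errors.append(RowError(lineno, oid, "malformed OID"))
                continue
            try:
                term = PrecoordinatedTerm(
                    oid=oid,
                    name=rec["name"].strip(),
                    organ=rec["organ"].strip() or None,
                    problem=rec["problem"].strip() or None,
                    category=Category(rec["category"].strip() or "observation"),
                    value_set=tuple(
                        v for v in rec["value_set"].split(dialect.value_set_sep) if v
                    ),
                )
            except ValueError as exc:
                result.errors.append(RowError(lineno, oid, str(exc)))
                continue
            result.terms.append(term)
    return result


def write_registry(
    terms: Iterable[PrecoordinatedTerm],
    path: str | Path,
    dialect: PathlexDialect = PathlexDialect(),
) -> None:
    path = Path(path)
    with path.open("w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(dialect.columns)
        for t in terms:
            writer.writerow(
                [
                    t.oid,
                    t.name,
                    t.organ or "",
                    t.problem or "",
                    t.category.value,
                    dialect.value_set_sep.join(t.value_set),
                ]
            )


# -- packaged table transcriptions ------------------------------------------


def _open_packaged(name: str):
    return (_DATA / name).open("r", encoding="utf-8")


def load_concept_table(name_or_path: str | Path) -> list[ConceptRef]:
    """Load one value-set table (targets/properties/qualifiers transcription).

    Columns: designation, snomed_code (may be empty), axis, approximate.
    Uncoded rows become local concepts so they remain usable in expressions.
    """
    if isinstance(name_or_path, str) and not Path(name_or_path).exists():
        fh = _open_packaged(name_or_path)
    else:
        fh = Path(name_or_path).open("r", encoding="utf-8")
    concepts: list[ConceptRef] = []
    with fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            designation = rec["designation"].strip()
            code = (rec.get("snomed_code") or "").strip()
            axis = Axis((rec.get("axis") or "").strip()) if (rec.get("axis") or "").strip() else None
            approximate = (rec.get("approximate") or "0").strip() == "1"
            if code:
                concepts.append(
                    ConceptRef(
                        code=code,
                        namespace=Namespace.SNOMED,
                        designation=designation,
                        axis=axis,
                        approximate=approximate,
                    )
                )
            else:
                concepts.append(
                    ConceptRef(
                        code=_slug(designation),
                        namespace=Namespace.LOCAL,
                        designation=designation,
                        axis=axis,
                    )
                )
    return concepts


def _slug(text: str) -> str:
    return re.sub(r"[^0-9A-Za-z._-]+", "-", text.strip()).strip("-")


def load_equivalence_table(name_or_path: str | Path = "equivalence.tsv") -> EquivalenceTable:
    """Load the packaged interface-element -> generic-element equivalences."""
    if isinstance(name_or_path, str) and not Path(name_or_path).exists():
        fh = _open_packaged(name_or_path)
    else:
        fh = Path(name_or_path).open("r", encoding="utf-8")
    rows: list[EquivalenceRow] = []
    with fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            extra = tuple(
                p for p in (rec.get("extra_patterns") or "").split("|") if p.strip()
            )
            quals = tuple(
                q for q in (rec.get("qualifiers") or "").split("|") if q.strip()
            )
            rows.append(
                EquivalenceRow(
                    oid=rec["oid"].strip(),
                    pattern=rec["pattern"].strip(),
                    generic_element=rec["generic_element"].strip(),
                    family=Family(rec["family"].strip()),
                    is_example=(rec.get("is_example") or "0").strip() == "1",
                    extra_patterns=extra,
                    recipe=Recipe(
                        target=rec["target"].strip(),
                        property=rec["property"].strip(),
                        method=(rec.get("method") or "").strip() or None,
                        qualifiers=quals,
                    ),
                    note=(rec.get("note") or "").strip(),
                )
            )
    return EquivalenceTable(rows)


# -- JSON -------------------------------------------------------------------


def concept_to_dict(c: ConceptRef) -> dict:
    d = {
        "code": c.code,
        "namespace": c.namespace.value,
        "designation": c.designation,
    }
    if c.axis is not None:
        d["axis"] = c.axis.value
    if c.approximate:
        d["approximate"] = True
    return d


def concept_from_dict(d: dict) -> ConceptRef:
    return ConceptRef(
        code=d["code"],
        namespace=Namespace(d["namespace"]),
        designation=d["designation"],
        axis=Axis(d["axis"]) if "axis" in d else None,
        approximate=bool(d.get("approximate", False)),
    )


def expression_to_dict(expr: GenericObservation) -> dict:
    """Canonical dictionary form of an expression (stable key order)."""
    d: dict = {
        "target": concept_to_dict(expr.target.concept),
        "property": concept_to_dict(expr.property.concept),
        "qualifiers": [concept_to_dict(q.concept) for q in expr.qualifiers],
        "context": {},
    }
    if expr.context.locator is not None:
        d["context"]["locator"] = concept_to_dict(expr.context.locator)
    if expr.context.problem is not None:
        d["context"]["problem"] = concept_to_dict(expr.context.problem)
    if expr.context.method is not None:
        d["context"]["method"] = concept_to_dict(expr.context.method.concept)
    if expr.value is not None:
        if expr.value.coded is not None:
            d["value"] = {"coded": concept_to_dict(expr.value.coded)}
        else:
            d["value"] = {"magnitude": expr.value.magnitude, "unit": expr.value.unit}
    return d


def expression_from_dict(d: dict, graph: OntologyGraph) -> GenericObservation:
    ctx = d.get("context", {})
    value = None
    if "value" in d:
        v = d["value"]
        if "coded" in v:
            value = ObservationValue(coded=concept_from_dict(v["coded"]))
        else:
            value = ObservationValue(magnitude=v["magnitude"], unit=v["unit"])
    return compose(
        graph,
        target=Target(concept_from_dict(d["target"])),
        property=Property(concept_from_dict(d["property"])),
        qualifiers=[Qualifier(concept_from_dict(q)) for q in d.get("qualifiers", [])],
        context=Context(
            locator=concept_from_dict(ctx["locator"]) if "locator" in ctx else None,
            problem=concept_from_dict(ctx["problem"]) if "problem" in ctx else None,
            method=Qualifier(concept_from_dict(ctx["method"])) if "method" in ctx else None,
        ),
        value=value,
    )


def expression_to_json(expr: GenericObservation) -> str:
    return json.dumps(expression_to_dict(expr), indent=2, sort_keys=True)


def expression_from_json(text: str, graph: OntologyGraph) -> GenericObservation:
    return expression_from_dict(json.loads(text), graph)


# -- XML --------------------------------------------------------------------


def _code_attrs(c: ConceptRef) -> dict[str, str]:
    attrs = {
        "code": c.code,
        "codeSystem": SNOMED_CT_OID if c.namespace is Namespace.SNOMED else LOCAL_CODESYSTEM_OID,
        "displayName": c.designation,
    }
    if c.approximate:
        attrs["approximate"] = "true"
    return attrs


def write_expression_xml(expr: GenericObservation) -> bytes:
    """Serialize to the package's HL7-template-style XML (deterministic).

    The property element points at the target element via ``ref`` and carries
    ``relationship="HAS-TARGET"``; qualifier and method elements carry
    ``relationship="IS-QUALIFIER-OF"``. Locator and problem organizer are
    sibling context elements. The document validates against the shipped XSD.
    """
    root = etree.Element(f"{{{XML_NS}}}genericObservation", nsmap={None: XML_NS})
    if expr.context.locator is not None:
        etree.SubElement(root, f"{{{XML_NS}}}locator", _code_attrs(expr.context.locator))
    if expr.context.problem is not None:
        etree.SubElement(
            root, f"{{{XML_NS}}}problemOrganizer", _code_attrs(expr.context.problem)
        )
    tgt_attrs = _code_attrs(expr.target.concept)
    tgt_attrs["id"] = "target"
    etree.SubElement(root, f"{{{XML_NS}}}target", tgt_attrs)
    prop_attrs = _code_attrs(expr.property.concept)
    prop_attrs.update({"relationship": "HAS-TARGET", "ref": "target"})
    etree.SubElement(root, f"{{{XML_NS}}}property", prop_attrs)
    for q in expr.qualifiers:
        q_attrs = _code_attrs(q.concept)
        q_attrs.update({"relationship": "IS-QUALIFIER-OF", "ref": "target"})
        etree.SubElement(root, f"{{{XML_NS}}}qualifier", q_attrs)
    if expr.context.method is not None:
        m_attrs = _code_attrs(expr.context.method.concept)
        m_attrs.update({"relationship": "IS-QUALIFIER-OF", "ref": "target"})
        etree.SubElement(root, f"{{{XML_NS}}}method", m_attrs)
    if expr.value is not None:
        val = etree.SubElement(root, f"{{{XML_NS}}}value")
        if expr.value.coded is not None:
            etree.SubElement(val, f"{{{XML_NS}}}code", _code_attrs(expr.value.coded))
        else:
            etree.SubElement(
                val,
                f"{{{XML_NS}}}quantity",
                {"value": repr(expr.value.magnitude), "unit": expr.value.unit},
            )
    doc = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    validate_expression_xml(doc)
    return doc


_schema_cache: etree.XMLSchema | None = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        with (_DATA / "observation.xsd").open("rb") as fh:
            _schema_cache = etree.XMLSchema(etree.parse(fh))
    return _schema_cache


def validate_expression_xml(doc: bytes) -> None:
    tree = etree.fromstring(doc)
    schema = _schema()
    if not schema.validate(tree):
        raise SerializationError(f"XML does not validate: {schema.error_log}")


def _concept_from_attrs(el: etree._Element) -> ConceptRef:
    ns = Namespace.SNOMED if el.get("codeSystem") == SNOMED_CT_OID else Namespace.LOCAL
    return ConceptRef(
        code=el.get("code"),
        namespace=ns,
        designation=el.get("displayName"),
        approximate=el.get("approximate") == "true",
    )


def parse_expression_xml(doc: bytes, graph: OntologyGraph) -> GenericObservation:
    validate_expression_xml(doc)
    root = etree.fromstring(doc)

    def find(tag: str):
        return root.find(f"{{{XML_NS}}}{tag}")

    locator_el = find("locator")
    problem_el = find("problemOrganizer")
    method_el = find("method")
    value_el = find("value")
    value = None
    if value_el is not None:
        code_el = value_el.find(f"{{{XML_NS}}}code")
        if code_el is not None:
            value = ObservationValue(coded=_concept_from_attrs(code_el))
        else:
            q = value_el.find(f"{{{XML_NS}}}quantity")
            value = ObservationValue(magnitude=float(q.get("value")), unit=q.get("unit"))
    return compose(
        graph,
        target=Target(_concept_from_attrs(find("target"))),
        property=Property(_concept_from_attrs(find("property"))),
        qualifiers=[
            Qualifier(_concept_from_attrs(el))
            for el in root.findall(f"{{{XML_NS}}}qualifier")
        ],
        context=Context(
            locator=_concept_from_attrs(locator_el) if locator_el is not None else None,
            problem=_concept_from_attrs(problem_el) if problem_el is not None else None,
            method=Qualifier(_concept_from_attrs(method_el)) if method_el is not None else None,
        ),
        value=value,
    )


# -- compositional grammar (parse side; rendering lives in model.to_scg) ----

_TERM_RE = re.compile(r"^\s*(?P<code>[0-9A-Za-z._-]+)\s*\|(?P<designation>[^|]*)\|\s*$")
_QTY_RE = re.compile(r"^\s*#(?P<mag>[-+0-9.eE]+)\s*\|(?P<unit>[^|]+)\|\s*$")


def _parse_scg_term(text: str, graph: OntologyGraph) -> ConceptRef:
    m = _TERM_RE.match(text)
    if not m:
        raise SerializationError(f"not a compositional-grammar term: {text!r}")
    code = m.group("code")
    if code.startswith(SCG_LOCAL_PREFIX):
        concept = ConceptRef(
            code=code[len(SCG_LOCAL_PREFIX):],
            namespace=Namespace.LOCAL,
            designation=m.group("designation"),
        )
    else:
        concept = ConceptRef(
            code=code, namespace=Namespace.SNOMED, designation=m.group("designation")
        )
    # prefer the registered concept so designations keep canonical casing
    if concept in graph:
        return graph.get(concept.code, concept.namespace)
    return concept


def parse_scg(text: str, graph: OntologyGraph) -> GenericObservation:
    """Parse the dialect emitted by :func:`pathterm.model.to_scg`."""
    if ":" in text:
        focus_text, _, rest = text.partition(":")
        parts = [p for p in rest.split(",") if p.strip()]
    else:
        focus_text, parts = text, []
    if not parts:
        raise SerializationError("expression must carry its property refinement")
    target = Target(_parse_scg_term(focus_text, graph))
    prop: Property | None = None
    qualifiers: list[Qualifier] = []
    locator = problem = None
    method = None
    value = None
    for i, part in enumerate(parts):
        if "=" not in part:
            if i != 0 or prop is not None:
                raise SerializationError(f"unexpected bare term: {part!r}")
            prop = Property(_parse_scg_term(part, graph))
            continue
        key, _, val_text = part.partition("=")
        key = key.strip()
        if key == "qualifier":
            qualifiers.append(Qualifier(_parse_scg_term(val_text, graph)))
        elif key == "method":
            method = Qualifier(_parse_scg_term(val_text, graph))
        elif key == "locator":
            locator = _parse_scg_term(val_text, graph)
        elif key == "problem":
            problem = _parse_scg_term(val_text, graph)
        elif key == "value":
            qty = _QTY_RE.match(val_text)
            if qty:
                value = ObservationValue(
                    magnitude=float(qty.group("mag")), unit=qty.group("unit")
                )
            else:
                value = ObservationValue(coded=_parse_scg_term(val_text, graph))
        else:
            raise SerializationError(f"unknown refinement key {key!r}")
    if prop is None:
        raise SerializationError("expression must carry its property refinement")
    return compose(
        graph,
        target=target,
        property=prop,
        qualifiers=qualifiers,
        context=Context(locator=locator, problem=problem, method=method),
        value=value,
    )
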