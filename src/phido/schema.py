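"""Core schema types for the patient health-information dialogue ontology.

The ontology T-Box is modelled as plain descriptors (classes, properties)
that can be serialized to OWL2 (Turtle or RDF/XML) and parsed back without
loss.  Classes carry a Searle speech-act annotation; properties cover the
object links between utterances, speech tasks, goals and discussions, plus
the five utterance data properties the dialogue engine relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, XSD, URIRef

__all__ = [
    "SPEECH_ACTS",
    "ClassDescriptor",
    "PropertyDescriptor",
    "OntologySchema",
    "Violation",
    "serialize_schema",
    "parse_schema",
    "validate_schema",
    "SchemaError",
]

#: Searle speech-act annotation values.  "assertive" and "representative"
#: are kept distinct because the source tables print both; "none" marks
#: classes with no act (unintelligible input, prattle, and every
#: non-utterance class).
SPEECH_ACTS = frozenset(
    {"assertive", "representative", "directive", "commissive",
     "expressive", "declaration", "none"}
)

#: The four top-level class hierarchies.
LEVEL_ROOTS = ("Discussion", "Goal", "Task", "Utterance")

#: Utterance classes that legitimately carry no speech act (input the
#: hearer could not classify).
NO_ACT_UTTERANCES = frozenset({"Unintelligible", "Prattle"})

#: The five utterance data properties, with their literal ranges.
DATA_PROPERTY_RANGES = {
    "hasUtterancePriority": "integer",
    "hasUtteranceString": "string",
    "hasBeenSaid": "boolean",
    "hasUtteranceExamples": "string",
    "hasFocus": "boolean",
}

#: Communication-goal subclasses (health-belief-model derived plus the
#: session bookends and the pursuit goal for hesitant participants).
COMMUNICATION_GOALS = (
    "Acclimate",
    "Conclude",
    "Communicate Benefit",
    "Communicate Effectiveness",
    "Communicate Harms",
    "Communicate Uncertainty",
    "Pursuit Before Exit",
)

#: Speech-task classes grouped by family.
SPEECH_TASKS = {
    "Pleasantry Task": ("Salutation", "Valediction"),
    "Proposition Task": (
        "Initiate Discussion",
        "Transition to Topic",
        "Interview Participant",
        "Discuss Health Topic",
    ),
    "Question and Answering Task": (),
}

_XSD_RANGES = {"string": XSD.string, "boolean": XSD.boolean, "integer": XSD.integer}
_XSD_BACK = {str(v): k for k, v in _XSD_RANGES.items()}


@dataclass(frozen=True)
class ClassDescriptor:
    """A named ontology class with its parents and speech-act annotation."""

    name: str
    parents: frozenset[str] = frozenset()
    speech_act: str = "none"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.speech_act not in SPEECH_ACTS:
            raise SchemaError(
                f"unknown speech act {self.speech_act!r} for class {self.name!r}; "
                f"expected one of {sorted(SPEECH_ACTS)}"
            )
        object.__setattr__(self, "parents", frozenset(self.parents))


@dataclass(frozen=True)
class PropertyDescriptor:
    """An object or data property of the schema."""

    name: str
    kind: str  # "object" | "data"
    domain: str = ""
    range: str = ""  # class name (object) or literal type (data)
    inverse_of: str | None = None
    sub_property_of: str | None = None
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("object", "data"):
            raise SchemaError(f"property kind must be 'object' or 'data', got {self.kind!r}")
        if self.kind == "data" and self.range not in _XSD_RANGES:
            raise SchemaError(
                f"data property {self.name!r} range must be one of "
                f"{sorted(_XSD_RANGES)}, got {self.range!r}"
            )


class SchemaError(ValueError):
    """Raised for malformed schema construction or serialization input."""


def camel_case(label: str) -> str:
    """IRI-safe local name: each word capitalized, spaces removed.

    Labels are kept verbatim in ``rdfs:label``, so the mapping need not be
    invertible on its own.
    """
    return "".join(w[:1].upper() + w[1:] for w in label.split())


@dataclass
class OntologySchema:
    """A T-Box: classes, properties and the namespace they live in."""

    classes: tuple[ClassDescriptor, ...] = ()
    properties: tuple[PropertyDescriptor, ...] = ()
    iri_base: str = "https://w3id.org/phido"

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.properties = tuple(self.properties)

    # -- lookup helpers -------------------------------------------------
    @property
    def class_map(self) -> dict[str, ClassDescriptor]:
        return {c.name: c for c in self.classes}

    @property
    def property_map(self) -> dict[str, PropertyDescriptor]:
        return {p.name: p for p in self.properties}

    def data_properties(self) -> list[PropertyDescriptor]:
        return [p for p in self.properties if p.kind == "data"]

    def object_properties(self) -> list[PropertyDescriptor]:
        return [p for p in self.properties if p.kind == "object"]

    def class_iri(self, name: str) -> URIRef:
        return URIRef(f"{self.iri_base}#{camel_case(name)}")

    def property_iri(self, name: str) -> URIRef:
        return URIRef(f"{self.iri_base}#{name}")

    def hierarchy(self) -> nx.DiGraph:
        """Child -> parent digraph over the declared classes."""
        g = nx.DiGraph()
        g.add_nodes_from(c.name for c in self.classes)
        for c in self.classes:
            for p in c.parents:
                g.add_edge(c.name, p)
        return g

    def ancestors(self, name: str) -> set[str]:
        g = self.hierarchy()
        if name not in g:
            return set()
        return set(nx.descendants(g, name))  # edges point child->parent

    def descendants_of(self, name: str) -> set[str]:
        g = self.hierarchy()
        if name not in g:
            return set()
        return set(nx.ancestors(g, name))

    def is_a(self, name: str, ancestor: str) -> bool:
        return name == ancestor or ancestor in self.ancestors(name)

    # -- equality: order-insensitive on classes and properties ----------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologySchema):
            return NotImplemented
        return (
            set(self.classes) == set(other.classes)
            and set(self.properties) == set(other.properties)
            and self.iri_base == other.iri_base
        )

    def __hash__(self) -> int:  # pragma: no cover - dict use only
        return hash((frozenset(self.classes), frozenset(self.properties), self.iri_base))


#: Annotation property carrying the Searle classification of a class.
SPEECH_ACT_PROPERTY = "hasSpeechActType"

_DIALECTS = {"turtle": "turtle", "rdfxml": "xml"}


def serialize_schema(schema: OntologySchema, dialect: str = "turtle") -> str:
    """Emit the schema as an OWL2 document (Turtle or RDF/XML)."""
    if dialect not in _DIALECTS:
        raise SchemaError(
            f"unknown dialect {dialect!r}; supported dialects: {sorted(_DIALECTS)}"
        )
    ns = Namespace(schema.iri_base + "#")
    g = Graph()
    g.bind("phido", ns)
    g.bind("owl", OWL)
    onto = URIRef(schema.iri_base)
    g.add((onto, RDF.type, OWL.Ontology))

    act_iri = schema.property_iri(SPEECH_ACT_PROPERTY)
    g.add((act_iri, RDF.type, OWL.AnnotationProperty))
    g.add((act_iri, RDFS.label, Literal(SPEECH_ACT_PROPERTY)))

    for c in schema.classes:
        iri = schema.class_iri(c.name)
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(c.name)))
        for parent in sorted(c.parents):
            g.add((iri, RDFS.subClassOf, schema.class_iri(parent)))
        if c.speech_act != "none":
            g.add((iri, act_iri, Literal(c.speech_act)))
        if c.annotation:
            g.add((iri, RDFS.comment, Literal(c.annotation)))

    for p in schema.properties:
        iri = schema.property_iri(p.name)
        g.add((iri, RDF.type, OWL.ObjectProperty if p.kind == "object" else OWL.DatatypeProperty))
        g.add((iri, RDFS.label, Literal(p.name)))
        if p.domain:
            g.add((iri, RDFS.domain, schema.class_iri(p.domain)))
        if p.range:
            rng = _XSD_RANGES[p.range] if p.kind == "data" else schema.class_iri(p.range)
            g.add((iri, RDFS.range, rng))
        if p.inverse_of:
            g.add((iri, OWL.inverseOf, schema.property_iri(p.inverse_of)))
        if p.sub_property_of:
            g.add((iri, RDFS.subPropertyOf, schema.property_iri(p.sub_property_of)))
        if p.symmetric:
            g.add((iri, RDF.type, OWL.SymmetricProperty))

    return g.serialize(format=_DIALECTS[dialect])


def parse_schema(document: str, dialect: str = "turtle") -> OntologySchema:
    """Parse an OWL2 document produced by :func:`serialize_schema`."""
    if dialect not in _DIALECTS:
        raise SchemaError(
            f"unknown dialect {dialect!r}; supported dialects: {sorted(_DIALECTS)}"
        )
    g = Graph()
    g.parse(data=document, format=_DIALECTS[dialect])

    onto = next(g.subjects(RDF.type, OWL.Ontology), None)
    iri_base = str(onto) if onto is not None else "https://w3id.org/phido"

    def label_of(iri: URIRef) -> str:
        lab = g.value(iri, RDFS.label)
        if lab is not None:
            return str(lab)
        # fall back to the IRI fragment
        return str(iri).rsplit("#", 1)[-1]

    act_iri = URIRef(f"{iri_base}#{SPEECH_ACT_PROPERTY}")

    class_iris = sorted(set(g.subjects(RDF.type, OWL.Class)))
    labels = {iri: label_of(iri) for iri in class_iris}
    classes = []
    for iri in class_iris:
        parents = frozenset(
            labels[p] for p in g.objects(iri, RDFS.subClassOf) if p in labels
        )
        act = g.value(iri, act_iri)
        comment = g.value(iri, RDFS.comment)
        classes.append(
            ClassDescriptor(
                name=labels[iri],
                parents=parents,
                speech_act=str(act) if act is not None else "none",
                annotation=str(comment) if comment is not None else "",
            )
        )

    properties = []
    for kind, rdf_type in (("object", OWL.ObjectProperty), ("data", OWL.DatatypeProperty)):
        for iri in sorted(set(g.subjects(RDF.type, rdf_type))):
            name = label_of(iri)
            domain = g.value(iri, RDFS.domain)
            rng = g.value(iri, RDFS.range)
            inverse = g.value(iri, OWL.inverseOf)
            sup = g.value(iri, RDFS.subPropertyOf)
            if kind == "data":
                range_name = _XSD_BACK.get(str(rng), "") if rng is not None else ""
            else:
                range_name = labels.get(rng, "") if rng is not None else ""
            properties.append(
                PropertyDescriptor(
                    name=name,
                    kind=kind,
                    domain=labels.get(domain, "") if domain is not None else "",
                    range=range_name,
                    inverse_of=label_of(inverse) if inverse is not None else None,
                    sub_property_of=label_of(sup) if sup is not None else None,
                    symmetric=(iri, RDF.type, OWL.SymmetricProperty) in g,
                )
            )

    return OntologySchema(tuple(classes), tuple(properties), iri_base=iri_base)


@dataclass(frozen=True)
class Violation:
    """One broken schema rule, naming the offending entity."""

    subject: str
    rule: str
    message: str


def validate_schema(schema: OntologySchema) -> list[Violation]:
    """Check every schema invariant; returns an empty list iff all hold.

    Reports violations rather than raising, so partially built or
    deliberately broken fixtures can be inspected.
    """
    out: list[Violation] = []

    # unique names (case-sensitive)
    seen: set[str] = set()
    for c in schema.classes:
        if c.name in seen:
            out.append(Violation(c.name, "duplicate-class", f"class {c.name!r} declared twice"))
        seen.add(c.name)
    pseen: set[str] = set()
    for p in schema.properties:
        if p.name in pseen:
            out.append(Violation(p.name, "duplicate-property", f"property {p.name!r} declared twice"))
        pseen.add(p.name)

    names = {c.name for c in schema.classes}
    pnames = {p.name for p in schema.properties}

    # parent references and acyclicity
    for c in schema.classes:
        for parent in c.parents:
            if parent not in names:
                out.append(Violation(c.name, "unknown-parent",
                                     f"class {c.name!r} names unknown parent {parent!r}"))
    g = schema.hierarchy()
    for cycle in nx.simple_cycles(g):
        out.append(Violation(cycle[0], "hierarchy-cycle",
                             "hierarchy cycle: " + " -> ".join(cycle + [cycle[0]])))

    # roots: only the four level roots may be parentless
    if nx.is_directed_acyclic_graph(g):
        for c in schema.classes:
            if not c.parents and c.name not in LEVEL_ROOTS:
                out.append(Violation(c.name, "orphan-class",
                                     f"non-root class {c.name!r} has no parent"))

    # speech-act rule: none only for non-utterance classes, the utterance
    # category roots, and the no-act classes
    if nx.is_directed_acyclic_graph(g) and "Utterance" in names:
        for c in schema.classes:
            below_pu = schema.is_a(c.name, "Participant Utterance") and c.name != "Participant Utterance"
            below_su = schema.is_a(c.name, "System Utterance") and c.name != "System Utterance"
            if (below_pu or below_su) and c.speech_act == "none" and c.name not in NO_ACT_UTTERANCES:
                out.append(Violation(c.name, "missing-speech-act",
                                     f"utterance class {c.name!r} lacks a speech act"))
            if not schema.is_a(c.name, "Utterance") and c.speech_act != "none":
                out.append(Violation(c.name, "spurious-speech-act",
                                     f"non-utterance class {c.name!r} carries a speech act"))

    # inverse mutuality
    pmap = schema.property_map
    for p in schema.properties:
        if p.inverse_of is not None:
            q = pmap.get(p.inverse_of)
            if q is None:
                out.append(Violation(p.name, "unknown-inverse",
                                     f"property {p.name!r} names unknown inverse {p.inverse_of!r}"))
            elif p.inverse_of == p.name or q.inverse_of != p.name:
                out.append(Violation(p.name, "inverse-not-mutual",
                                     "inverse must be mutual and distinct: "
                                     f"{p.name!r} <-> {p.inverse_of!r}"))
        if p.sub_property_of is not None and p.sub_property_of not in pnames:
            out.append(Violation(p.name, "unknown-super-property",
                                 f"property {p.name!r} names unknown super-property "
                                 f"{p.sub_property_of!r}"))

    # exactly the five data properties
    declared = {p.name: p.range for p in schema.data_properties()}
    for name, rng in DATA_PROPERTY_RANGES.items():
        if name not in declared:
            out.append(Violation(name, "missing-data-property",
                                 f"required data property {name!r} is missing"))
        elif declared[name] != rng:
            out.append(Violation(name, "wrong-data-range",
                                 f"data property {name!r} must range over {rng!r}, "
                                 f"got {declared[name]!r}"))
    for name in declared:
        if name not in DATA_PROPERTY_RANGES:
            out.append(Violation(name, "extra-data-property",
                                 f"unexpected data property {name!r}"))

    # structural inventory
    for root in LEVEL_ROOTS:
        if root not in names:
            out.append(Violation(root, "missing-root", f"level root {root!r} is missing"))
    if "Utterance" in names:
        direct = sorted(c.name for c in schema.classes if "Utterance" in c.parents)
        if direct != ["Participant Utterance", "System Utterance"]:
            out.append(Violation("Utterance", "utterance-subclasses",
                                 "Utterance must have exactly the direct subclasses "
                                 f"Participant Utterance and System Utterance, got {direct}"))
    for goal in COMMUNICATION_GOALS:
        if goal not in names:
            out.append(Violation(goal, "missing-goal",
                                 f"communication goal {goal!r} is missing"))
    for family, members in SPEECH_TASKS.items():
        for t in (family,) + members:
            if t not in names:
                out.append(Violation(t, "missing-speech-task",
                                     f"speech-task class {t!r} is missing"))

    return out
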