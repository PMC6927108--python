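"""Semiotic quality metrics for OWL2 ontologies.

The suite scores an ontology along three semiotic branches:

* syntactic — ``lawfulness`` (1 minus the fraction of statements that
  break the OWL2 profile) and ``richness`` (the fraction of a fixed
  axiom-type inventory the ontology actually uses);
* semantic — ``interpretability`` (fraction of label words found in a
  lexicon), ``consistency`` (fraction of classes satisfiable under
  structural reasoning), and ``clarity`` (mean inverse sense count of
  label words, penalizing ambiguous terms);
* pragmatic — ``comprehensiveness`` (ontology size relative to the
  average size of a reference library).

Branch scores are the unweighted means of their sub-scores, and the
overall score is the weighted mean of the branches (default weight 1/3
each).  All scores live in [0, 1].  Z-scores against a benchmark sample
of other ontologies can be computed when the benchmark's per-score mean
and standard deviation are supplied; no benchmark is built in.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping

from rdflib import Graph, RDF, RDFS, OWL, XSD, URIRef, BNode, Literal

from .lexicon import toy_sense_count

__all__ = [
    "MetricConfig",
    "MetricReport",
    "CompositeScores",
    "DEFAULT_AXIOM_INVENTORY",
    "load_ontology",
    "lawfulness",
    "richness",
    "interpretability",
    "consistency",
    "clarity",
    "comprehensiveness",
    "compose",
    "zscores",
    "evaluate",
]

#: Recognized OWL2 axiom/feature types for the richness denominator.
DEFAULT_AXIOM_INVENTORY: tuple[str, ...] = (
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "DisjointUnion",
    "SubPropertyOf",
    "InverseProperties",
    "SymmetricProperty",
    "TransitiveProperty",
    "FunctionalProperty",
    "InverseFunctionalProperty",
    "PropertyDomain",
    "PropertyRange",
    "ClassAssertion",
    "ObjectPropertyAssertion",
    "DataPropertyAssertion",
    "AnnotationAssertion",
)

_DIALECTS = {"turtle": "turtle", "rdfxml": "xml"}

_CORE_NAMESPACES = (str(RDF), str(RDFS), str(OWL), str(XSD))

_CORE_TYPE_OBJECTS = {
    OWL.Ontology, OWL.Class, OWL.ObjectProperty, OWL.DatatypeProperty,
    OWL.AnnotationProperty, OWL.SymmetricProperty, OWL.TransitiveProperty,
    OWL.FunctionalProperty, OWL.InverseFunctionalProperty,
    OWL.NamedIndividual, OWL.Restriction, RDFS.Class, RDF.Property,
}

_PROPERTY_TYPES = (OWL.ObjectProperty, OWL.DatatypeProperty, OWL.AnnotationProperty)


class MetricsError(ValueError):
    """Bad metric input (unparseable ontology, out-of-range score)."""


def load_ontology(document: str, dialect: str = "turtle") -> Graph:
    """Parse an ontology document into a triple graph."""
    if dialect not in _DIALECTS:
        raise MetricsError(
            f"unknown dialect {dialect!r}; supported dialects: {sorted(_DIALECTS)}"
        )
    g = Graph()
    try:
        g.parse(data=document, format=_DIALECTS[dialect])
    except Exception as exc:  # rdflib raises many parser-specific types
        raise MetricsError(f"unparseable ontology document: {exc}") from exc
    return g


def _as_graph(ontology: str | Graph, dialect: str = "turtle") -> Graph:
    if isinstance(ontology, Graph):
        return ontology
    return load_ontology(ontology, dialect)


def _declared(g: Graph, *types) -> set:
    out = set()
    for t in types:
        out |= set(g.subjects(RDF.type, t))
    return out


def _is_core(term) -> bool:
    return isinstance(term, URIRef) and str(term).startswith(_CORE_NAMESPACES)


# ---------------------------------------------------------------------------
# syntactic branch

def lawfulness(ontology: str | Graph, dialect: str = "turtle") -> float:
    """1 minus the fraction of profile-violating statements.

    Violations counted: use of undeclared predicates, typing against
    undeclared classes, sub-classing undeclared terms, and punning (one
    IRI declared as both a class and a property, or as both an object
    and a data property).  An empty ontology scores 1.0 by convention.
    """
    g = _as_graph(ontology, dialect)
    total = len(g)
    if total == 0:
        return 1.0

    classes = _declared(g, OWL.Class, RDFS.Class)
    props = _declared(g, *_PROPERTY_TYPES)
    obj_props = _declared(g, OWL.ObjectProperty)
    data_props = _declared(g, OWL.DatatypeProperty)

    punned = (classes & props) | (obj_props & data_props)

    bad: set = set()
    for s, p, o in g:
        if s in punned or (isinstance(o, URIRef) and o in punned and p == RDF.type):
            bad.add((s, p, o))
            continue
        if not _is_core(p) and p not in props:
            bad.add((s, p, o))
            continue
        if p == RDF.type and isinstance(o, URIRef):
            if o not in _CORE_TYPE_OBJECTS and not _is_core(o) and o not in classes:
                bad.add((s, p, o))
        elif p == RDFS.subClassOf:
            if (s not in classes) or (
                isinstance(o, URIRef) and o not in classes and not _is_core(o)
            ):
                bad.add((s, p, o))
            elif isinstance(o, BNode) and (o, RDF.type, OWL.Restriction) not in g:
                bad.add((s, p, o))
        elif p in (RDFS.domain, RDFS.range):
            if isinstance(o, URIRef) and not _is_core(o) and o not in classes:
                bad.add((s, p, o))
    return 1.0 - len(bad) / total


def _axiom_types_used(g: Graph) -> set[str]:
    classes = _declared(g, OWL.Class)
    obj_props = _declared(g, OWL.ObjectProperty)
    data_props = _declared(g, OWL.DatatypeProperty)
    ann_props = _declared(g, OWL.AnnotationProperty)

    used: set[str] = set()
    checks: list[tuple[str, bool]] = [
        ("SubClassOf", (None, RDFS.subClassOf, None) in g),
        ("EquivalentClasses", (None, OWL.equivalentClass, None) in g),
        ("DisjointClasses", (None, OWL.disjointWith, None) in g),
        ("DisjointUnion", (None, OWL.disjointUnionOf, None) in g),
        ("SubPropertyOf", (None, RDFS.subPropertyOf, None) in g),
        ("InverseProperties", (None, OWL.inverseOf, None) in g),
        ("SymmetricProperty", (None, RDF.type, OWL.SymmetricProperty) in g),
        ("TransitiveProperty", (None, RDF.type, OWL.TransitiveProperty) in g),
        ("FunctionalProperty", (None, RDF.type, OWL.FunctionalProperty) in g),
        ("InverseFunctionalProperty", (None, RDF.type, OWL.InverseFunctionalProperty) in g),
        ("PropertyDomain", (None, RDFS.domain, None) in g),
        ("PropertyRange", (None, RDFS.range, None) in g),
    ]
    for name, present in checks:
        if present:
            used.add(name)
    for s, p, o in g:
        if p == RDF.type and o in classes:
            used.add("ClassAssertion")
        elif p in obj_props:
            used.add("ObjectPropertyAssertion")
        elif p in data_props and isinstance(o, Literal):
            used.add("DataPropertyAssertion")
        elif p in ann_props or p in (RDFS.label, RDFS.comment):
            used.add("AnnotationAssertion")
    return used


def richness(ontology: str | Graph,
             inventory: tuple[str, ...] = DEFAULT_AXIOM_INVENTORY,
             dialect: str = "turtle") -> float:
    """Fraction of the axiom-type inventory the ontology uses."""
    if not inventory:
        raise MetricsError("axiom inventory must be non-empty")
    g = _as_graph(ontology, dialect)
    used = _axiom_types_used(g)
    return len(used & set(inventory)) / len(inventory)


# ---------------------------------------------------------------------------
# semantic branch

_CAMEL_RE = re.compile(r"[A-Z]?[a-z]+|[A-Z]+(?![a-z])|\d+")


def _label_words(g: Graph) -> set[str]:
    """Distinct lower-cased words from entity labels (camel/space split)."""
    labels: list[str] = [str(o) for o in g.objects(None, RDFS.label)]
    if not labels:
        for subject in _declared(g, OWL.Class, *_PROPERTY_TYPES):
            labels.append(str(subject).rsplit("#", 1)[-1].rsplit("/", 1)[-1])
    words: set[str] = set()
    for lab in labels:
        for chunk in lab.replace("_", " ").split():
            words.update(w.lower() for w in _CAMEL_RE.findall(chunk))
    return words


def interpretability(ontology: str | Graph,
                     lexical_provider: Callable[[str], int] = toy_sense_count,
                     dialect: str = "turtle") -> float:
    """Fraction of distinct label words with at least one lexicon sense."""
    words = _label_words(_as_graph(ontology, dialect))
    if not words:
        return 1.0
    return sum(1 for w in words if lexical_provider(w) >= 1) / len(words)


def clarity(ontology: str | Graph,
            lexical_provider: Callable[[str], int] = toy_sense_count,
            dialect: str = "turtle") -> float:
    """Mean inverse sense count of label words (1.0 = fully monosemous).

    Unknown words (0 senses) are clamped to one sense and so contribute
    1.0: a word the lexicon does not know cannot be charged as ambiguous.
    """
    words = _label_words(_as_graph(ontology, dialect))
    if not words:
        return 1.0
    return sum(1.0 / max(1, lexical_provider(w)) for w in words) / len(words)


def consistency(ontology: str | Graph, dialect: str = "turtle") -> float:
    """Fraction of classes satisfiable under structural reasoning.

    A class is unsatisfiable when its reflexive-transitive superclass set
    contains two classes asserted disjoint (or a class disjoint with
    itself).  No description-logic reasoner is involved; this covers
    schemas without complex class expressions.
    """
    g = _as_graph(ontology, dialect)
    classes = _declared(g, OWL.Class)
    if not classes:
        return 1.0

    parents: dict = {c: set() for c in classes}
    for s, _, o in g.triples((None, RDFS.subClassOf, None)):
        if s in classes and o in classes:
            parents[s].add(o)

    disjoint: set[frozenset] = set()
    for s, _, o in g.triples((None, OWL.disjointWith, None)):
        disjoint.add(frozenset((s, o)))

    def ancestors(c) -> set:
        seen, stack = {c}, [c]
        while stack:
            for p in parents.get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    satisfiable = 0
    for c in classes:
        anc = ancestors(c)
        clash = any(
            frozenset((a, b)) in disjoint or (a == b and frozenset((a,)) in disjoint)
            for a in anc for b in anc
        )
        if not clash:
            satisfiable += 1
    return satisfiable / len(classes)


# ---------------------------------------------------------------------------
# pragmatic branch

def comprehensiveness(ontology: str | Graph, reference_size: float = 10000.0,
                      dialect: str = "turtle") -> float:
    """Ontology size (class count) relative to a reference library average."""
    if reference_size <= 0:
        raise MetricsError("reference size must be positive")
    g = _as_graph(ontology, dialect)
    n = len(_declared(g, OWL.Class))
    return min(1.0, n / reference_size)


# ---------------------------------------------------------------------------
# composites

@dataclass(frozen=True)
class CompositeScores:
    """Branch scores and the weighted overall score (None if underdetermined)."""

    syntactic: float | None = None
    semantic: float | None = None
    pragmatic: float | None = None
    overall: float | None = None


def _check_range(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise MetricsError(f"score {name!r} must lie in [0, 1], got {value}")
    return float(value)


def compose(scores: Mapping[str, float],
            weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)) -> CompositeScores:
    """Combine sub-scores (and/or branch scores) into the composites.

    syntactic = mean(lawfulness, richness); semantic = mean of
    interpretability, consistency, clarity; pragmatic =
    comprehensiveness.  Branch values supplied directly take precedence
    over recomputation from sub-scores.  overall = sum of weighted
    branches, computed only when all three branches are determined.
    """
    if any(w < 0 for w in weights):
        raise MetricsError("branch weights must be non-negative")
    vals = {k: _check_range(k, v) for k, v in scores.items()}

    def mean(keys):
        if all(k in vals for k in keys):
            return sum(vals[k] for k in keys) / len(keys)
        return None

    syntactic = vals.get("syntactic", mean(("lawfulness", "richness")))
    semantic = vals.get("semantic", mean(("interpretability", "consistency", "clarity")))
    pragmatic = vals.get("pragmatic", vals.get("comprehensiveness"))
    overall = None
    if None not in (syntactic, semantic, pragmatic):
        overall = (weights[0] * syntactic + weights[1] * semantic
                   + weights[2] * pragmatic)
    return CompositeScores(syntactic, semantic, pragmatic, overall)


def zscores(report_scores: Mapping[str, float],
            benchmark: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Standardize scores against a benchmark's per-score (mean, sd).

    Entries without a benchmark are omitted; a non-positive sd is an
    error.
    """
    out: dict[str, float] = {}
    for name, stats in benchmark.items():
        if name not in report_scores:
            continue
        sd = stats["sd"]
        if sd <= 0:
            raise MetricsError(f"benchmark sd for {name!r} must be positive")
        out[name] = (report_scores[name] - stats["mean"]) / sd
    return out


# ---------------------------------------------------------------------------
# one-call evaluation

@dataclass
class MetricConfig:
    """Configuration for a full metric evaluation."""

    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    axiom_inventory: tuple[str, ...] = DEFAULT_AXIOM_INVENTORY
    lexical_provider: Callable[[str], int] = toy_sense_count
    benchmark: dict[str, dict[str, float]] | None = None
    comprehensiveness_reference: float = 10000.0

    def __post_init__(self) -> None:
        if not self.axiom_inventory:
            raise MetricsError("axiom inventory must be non-empty")
        if any(w < 0 for w in self.weights):
            raise MetricsError("branch weights must be non-negative")


@dataclass
class MetricReport:
    """Six sub-scores, the composites, and optional benchmark z-scores."""

    lawfulness: float
    richness: float
    interpretability: float
    consistency: float
    clarity: float
    comprehensiveness: float
    syntactic: float
    semantic: float
    pragmatic: float
    overall: float
    zscores: dict[str, float] = field(default_factory=dict)

    def sub_scores(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "lawfulness", "richness", "interpretability", "consistency",
            "clarity", "comprehensiveness")}

    def as_dict(self, ndigits: int | None = None) -> dict:
        data = {k: getattr(self, k) for k in (
            "lawfulness", "richness", "interpretability", "consistency",
            "clarity", "comprehensiveness", "syntactic", "semantic",
            "pragmatic", "overall")}
        if ndigits is not None:
            data = {k: round(v, ndigits) for k, v in data.items()}
        if self.zscores:
            data["zscores"] = {
                k: (round(v, ndigits) if ndigits is not None else v)
                for k, v in self.zscores.items()
            }
        return data

    def to_json(self, ndigits: int | None = 2) -> str:
        return json.dumps(self.as_dict(ndigits), indent=2, sort_keys=True) + "\n"


def evaluate(ontology: str | Graph, config: MetricConfig | None = None,
             dialect: str = "turtle") -> MetricReport:
    """Score one ontology with the full suite under a configuration."""
    cfg = config or MetricConfig()
    g = _as_graph(ontology, dialect)
    subs = {
        "lawfulness": lawfulness(g),
        "richness": richness(g, cfg.axiom_inventory),
        "interpretability": interpretability(g, cfg.lexical_provider),
        "consistency": consistency(g),
        "clarity": clarity(g, cfg.lexical_provider),
        "comprehensiveness": comprehensiveness(g, cfg.comprehensiveness_reference),
    }
    comp = compose(subs, cfg.weights)
    report = MetricReport(
        **subs,
        syntactic=comp.syntactic, semantic=comp.semantic,
        pragmatic=comp.pragmatic, overall=comp.overall,
    )
    if cfg.benchmark:
        all_scores = {**subs, "syntactic": comp.syntactic,
                      "semantic": comp.semantic, "pragmatic": comp.pragmatic,
                      "overall": comp.overall}
        report.zscores = zscores(all_scores, cfg.benchmark)
    return report
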