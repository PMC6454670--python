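"""Typed graph model for an RDF-style medical knowledge base.

The knowledge base is a pair ``O = (G_s, G_d)``:

* a **schema graph** :class:`SchemaGraph` holding classes (C), relations (R),
  attributes (A) and datatypes (D), connected by the four axiom edge labels
  ``rdfs:domain``, ``rdfs:range``, ``rdfs:subClassOf`` and ``owl:disjointWith``;
* a **data graph** :class:`DataGraph` holding instances (I) and data values
  (V), connected by relation edges (I -> I), attribute edges (I -> V) and
  ``rdf:type`` membership edges pointing at schema classes.

:func:`validate` checks a data graph against its companion schema and returns
:class:`Violation` records instead of raising, so noisy extracted data can be
inspected and repaired (the fusion stage depends on this).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator

RDF_TYPE = "rdf:type"
DOMAIN = "rdfs:domain"
RANGE = "rdfs:range"
SUBCLASS_OF = "rdfs:subClassOf"
DISJOINT_WITH = "owl:disjointWith"

#: the only edge labels a schema graph may carry
SCHEMA_EDGE_LABELS = frozenset({DOMAIN, RANGE, SUBCLASS_OF, DISJOINT_WITH})

#: prefix for data-value vertex identifiers (one shared vertex per distinct value)
VALUE_PREFIX = "value:"

Triple = tuple[str, str, str]


def normalize_label(text: str) -> str:
    """Whitespace-collapse and case-fold a label for comparisons."""
    return " ".join(text.split()).casefold()


def value_id(label: str) -> str:
    """Deterministic vertex id for a data value (shared across sources)."""
    return VALUE_PREFIX + label


@dataclass(frozen=True)
class SchemaVertex:
    id: str
    kind: str  # one of C, R, A, D
    label: str


@dataclass(frozen=True)
class DataVertex:
    id: str
    kind: str  # I (instance) or V (data value)
    label: str
    source: str | None = None


@dataclass(frozen=True)
class Violation:
    """One breached restriction found by :func:`validate`.

    ``rule`` is one of ``domain``, ``range``, ``disjoint``, ``type-target``,
    ``edge-kind``; ``subject`` names the offending edge or vertex/class pair.
    """

    rule: str
    subject: tuple
    message: str

    RULES = frozenset({"domain", "range", "disjoint", "type-target", "edge-kind"})

    def __post_init__(self) -> None:
        if self.rule not in self.RULES:
            raise ValueError(f"unknown violation rule {self.rule!r}")


class SchemaGraph:
    """Schema graph G_s: typed vertices plus the four axiom edge labels."""

    def __init__(self) -> None:
        self.vertices: dict[str, SchemaVertex] = {}
        self.edges: set[Triple] = set()

    # -- construction -------------------------------------------------

    def add_vertex(self, id: str, kind: str, label: str | None = None) -> str:
        if kind not in ("C", "R", "A", "D"):
            raise ValueError(f"schema vertex kind must be C/R/A/D, got {kind!r}")
        vertex = SchemaVertex(id, kind, label if label is not None else id)
        existing = self.vertices.get(id)
        if existing is not None and existing != vertex:
            raise ValueError(f"conflicting redefinition of schema vertex {id!r}")
        self.vertices[id] = vertex
        return id

    def add_class(self, id: str, label: str | None = None) -> str:
        return self.add_vertex(id, "C", label)

    def add_datatype(self, id: str, label: str | None = None) -> str:
        return self.add_vertex(id, "D", label)

    def add_relation(self, id: str, domain: str, range_: str,
                     label: str | None = None) -> str:
        self.add_vertex(id, "R", label)
        self.add_edge(id, DOMAIN, domain)
        self.add_edge(id, RANGE, range_)
        return id

    def add_attribute(self, id: str, range_: str, domain: str | None = None,
                      label: str | None = None) -> str:
        self.add_vertex(id, "A", label)
        self.add_edge(id, RANGE, range_)
        if domain is not None:
            self.add_edge(id, DOMAIN, domain)
        return id

    def add_edge(self, source: str, label: str, target: str) -> None:
        if label not in SCHEMA_EDGE_LABELS:
            raise ValueError(f"not a schema edge label: {label!r}")
        s = self.vertices.get(source)
        t = self.vertices.get(target)
        if s is None or t is None:
            raise ValueError(f"schema edge endpoints must exist: ({source}, {label}, {target})")
        ok = {
            DOMAIN: s.kind in ("A", "R") and t.kind == "C",
            RANGE: (s.kind == "A" and t.kind == "D") or (s.kind == "R" and t.kind == "C"),
            SUBCLASS_OF: s.kind == "C" and t.kind == "C",
            DISJOINT_WITH: s.kind == "C" and t.kind == "C",
        }[label]
        if not ok:
            raise ValueError(
                f"edge {label} not allowed between kinds {s.kind} and {t.kind}"
            )
        self.edges.add((source, label, target))

    # -- queries ------------------------------------------------------

    def _ids_of_kind(self, kind: str) -> set[str]:
        return {v.id for v in self.vertices.values() if v.kind == kind}

    def classes(self) -> set[str]:
        return self._ids_of_kind("C")

    def relations(self) -> set[str]:
        return self._ids_of_kind("R")

    def attributes(self) -> set[str]:
        return self._ids_of_kind("A")

    def datatypes(self) -> set[str]:
        return self._ids_of_kind("D")

    def leaf_classes(self) -> set[str]:
        """Classes that are not the superclass of anything (structural
        superclasses such as Medicine are excluded)."""
        parents = {t for (_, l, t) in self.edges if l == SUBCLASS_OF}
        return self.classes() - parents

    def domain_of(self, prop: str) -> str | None:
        for s, l, t in self.edges:
            if s == prop and l == DOMAIN:
                return t
        return None

    def range_of(self, prop: str) -> str | None:
        for s, l, t in self.edges:
            if s == prop and l == RANGE:
                return t
        return None

    def superclasses(self, cls: str) -> set[str]:
        """Reflexive-transitive superclass closure of ``cls``."""
        out = {cls}
        frontier = [cls]
        while frontier:
            c = frontier.pop()
            for s, l, t in self.edges:
                if l == SUBCLASS_OF and s == c and t not in out:
                    out.add(t)
                    frontier.append(t)
        return out

    def declared_disjoint(self) -> set[frozenset]:
        """Declared disjoint pairs, closed under symmetry."""
        return {frozenset((s, t)) for (s, l, t) in self.edges if l == DISJOINT_WITH}

    def is_disjoint(self, c1: str, c2: str) -> bool:
        """Whether two classes are disjoint, inheriting disjointness from
        any pair of (reflexive) ancestors."""
        if c1 == c2:
            return False
        sup1, sup2 = self.superclasses(c1), self.superclasses(c2)
        if c1 in sup2 or c2 in sup1:  # ancestor/descendant, never disjoint
            return False
        declared = self.declared_disjoint()
        return any(frozenset((a, b)) in declared for a in sup1 for b in sup2)

    def class_by_label(self, label: str) -> str | None:
        """Resolve a (normalized) class label or id to a class id."""
        wanted = normalize_label(label)
        for cid in self.classes():
            v = self.vertices[cid]
            if normalize_label(v.label) == wanted or normalize_label(cid) == wanted:
                return cid
        return None

    def check(self) -> list[str]:
        """Schema-level sanity problems (empty list when well-formed)."""
        problems = []
        for pair in self.declared_disjoint():
            if len(pair) == 1:
                problems.append(f"class {next(iter(pair))!r} disjoint with itself")
                continue
            a, b = sorted(pair)
            if a in self.superclasses(b) or b in self.superclasses(a):
                problems.append(f"disjoint pair ({a}, {b}) are ancestor/descendant")
        for rid in self.relations():
            if self.domain_of(rid) is None or self.range_of(rid) is None:
                problems.append(f"relation {rid!r} lacks a domain or range")
        return problems


class DataGraph:
    """Data graph G_d: instance and value vertices with (s, p, o) edges."""

    def __init__(self) -> None:
        self.vertices: dict[str, DataVertex] = {}
        self.edges: set[Triple] = set()

    # -- construction -------------------------------------------------

    def _add(self, vertex: DataVertex) -> str:
        existing = self.vertices.get(vertex.id)
        if existing is not None and existing != vertex:
            raise ValueError(
                f"conflicting redefinition of vertex {vertex.id!r}: "
                f"{existing} vs {vertex}"
            )
        self.vertices[vertex.id] = vertex
        return vertex.id

    def add_instance(self, id: str, label: str, source: str | None = None) -> str:
        return self._add(DataVertex(id, "I", label, source))

    def add_value(self, label: str) -> str:
        return self._add(DataVertex(value_id(label), "V", label))

    def add_edge(self, s: str, p: str, o: str) -> None:
        # no schema checks here; validate() reports inconsistencies
        self.edges.add((s, p, o))

    def copy(self) -> "DataGraph":
        g = DataGraph()
        g.vertices = dict(self.vertices)
        g.edges = set(self.edges)
        return g

    # -- queries ------------------------------------------------------

    def instances(self) -> Iterator[DataVertex]:
        return (v for v in self.vertices.values() if v.kind == "I")

    def instance_ids(self) -> set[str]:
        return {v.id for v in self.vertices.values() if v.kind == "I"}

    @property
    def n_instances(self) -> int:
        return sum(1 for _ in self.instances())

    def type_map(self) -> dict[str, set[str]]:
        """instance id -> set of asserted class ids (any target of rdf:type)."""
        out: dict[str, set[str]] = defaultdict(set)
        for s, p, o in self.edges:
            if p == RDF_TYPE:
                out[s].add(o)
        return dict(out)

    def types_of(self, id: str) -> set[str]:
        return {o for (s, p, o) in self.edges if p == RDF_TYPE and s == id}

    def relation_edges(self) -> set[Triple]:
        """Edges between two instance vertices (the L_R edges)."""
        verts = self.vertices
        return {
            (s, p, o)
            for (s, p, o) in self.edges
            if p != RDF_TYPE
            and s in verts and o in verts
            and verts[s].kind == "I" and verts[o].kind == "I"
        }

    def attribute_edges(self) -> set[Triple]:
        """Edges from an instance to a value vertex (the L_A edges)."""
        verts = self.vertices
        return {
            (s, p, o)
            for (s, p, o) in self.edges
            if p != RDF_TYPE
            and s in verts and o in verts
            and verts[s].kind == "I" and verts[o].kind == "V"
        }


def validate(data: DataGraph, schema: SchemaGraph) -> list[Violation]:
    """Check a data graph against a schema; one :class:`Violation` per breach.

    Rules, in the order reported:

    * ``edge-kind`` — an edge label must be a known relation (I -> I),
      attribute (I -> V) or ``rdf:type``; endpoints must have the right kinds.
    * ``type-target`` — the object of ``rdf:type`` must be a declared class.
    * ``domain`` / ``range`` — a relation edge whose typed subject (object)
      carries no class compatible with the relation's declared domain (range).
      Untyped endpoints are not reported (open world: the type may simply be
      missing from this source).
    * ``disjoint`` — an instance typed with two disjoint classes, reported
      once per (instance, class pair).
    """
    out: list[Violation] = []
    relations = schema.relations()
    attributes = schema.attributes()
    classes = schema.classes()
    verts = data.vertices

    types: dict[str, set[str]] = defaultdict(set)
    for s, p, o in data.edges:
        if p == RDF_TYPE and o in classes:
            types[s].add(o)

    def kind(v: str) -> str | None:
        dv = verts.get(v)
        return dv.kind if dv is not None else None

    for s, p, o in sorted(data.edges):
        if p == RDF_TYPE:
            if kind(s) != "I":
                out.append(Violation("edge-kind", (s, p, o),
                                     "rdf:type subject must be an instance vertex"))
            if o not in classes:
                out.append(Violation("type-target", (s, p, o),
                                     f"rdf:type target {o!r} is not a schema class"))
        elif p in relations:
            if kind(s) != "I" or kind(o) != "I":
                out.append(Violation("edge-kind", (s, p, o),
                                     f"relation {p!r} must connect two instances"))
                continue
            dom = schema.domain_of(p)
            if dom is not None and types.get(s):
                if not any(dom in schema.superclasses(t) for t in types[s]):
                    out.append(Violation("domain", (s, p, o),
                                         f"subject types {sorted(types[s])} are not "
                                         f"subclasses of {dom!r}"))
            ran = schema.range_of(p)
            if ran is not None and types.get(o):
                if not any(ran in schema.superclasses(t) for t in types[o]):
                    out.append(Violation("range", (s, p, o),
                                         f"object types {sorted(types[o])} are not "
                                         f"subclasses of {ran!r}"))
        elif p in attributes:
            if kind(s) != "I" or kind(o) != "V":
                out.append(Violation("edge-kind", (s, p, o),
                                     f"attribute {p!r} must connect an instance "
                                     f"to a data value"))
        else:
            out.append(Violation("edge-kind", (s, p, o),
                                 f"unknown edge label {p!r}"))

    for inst in sorted(types):
        for c1, c2 in combinations(sorted(types[inst]), 2):
            if schema.is_disjoint(c1, c2):
                out.append(Violation("disjoint", (inst, c1, c2),
                                     f"instance typed with disjoint classes "
                                     f"{c1!r} and {c2!r}"))
    return out


def merge_graphs(graphs: Iterable[DataGraph]) -> DataGraph:
    """Union a collection of data graphs into one.

    Vertex ids are expected to be namespaced by source, so instance sets are
    disjoint; shared value vertices (same value, same deterministic id) merge
    silently. A duplicated id with a conflicting label or kind signals a
    malformed input and raises ``ValueError``. The edge multiset is
    deduplicated per (s, p, o).
    """
    out = DataGraph()
    for g in graphs:
        for v in g.vertices.values():
            out._add(v)
        out.edges |= g.edges
    return out


# ---------------------------------------------------------------------------
# default diabetes-domain schema

#: the seven leaf classes of the diabetes KB
LEAF_CLASSES = (
    ("Disease", "Disease"),
    ("Symptom", "Symptom"),
    ("TCM", "Traditional Chinese Medicine"),
    ("WesternMedicine", "Western Medicine"),
    ("Department", "Department"),
    ("BodyStructure", "Body Structure"),
    ("Examination", "Examination"),
)

#: the ten relations: id, domain class, range class
RELATIONS = (
    ("sign", "Disease", "Symptom"),
    ("complication", "Disease", "Disease"),
    ("causes", "Disease", "Disease"),
    ("risk_factor", "Disease", "Disease"),
    ("related_disease", "Disease", "Disease"),
    ("treated_by_wm", "Disease", "WesternMedicine"),
    ("treated_by_tcm", "Disease", "TCM"),
    ("checked_by_exam", "Disease", "Examination"),
    ("belongs_to_dept", "Disease", "Department"),
    ("located_in_body", "Disease", "BodyStructure"),
)


def default_diabetes_schema() -> SchemaGraph:
    """The shipped diabetes-domain schema.

    Seven leaf classes (Disease, Symptom, Traditional Chinese Medicine,
    Western Medicine, Department, Body Structure, Examination), a structural
    ``Medicine`` superclass over the two medicine classes, ten relations with
    disease-centric domains (e.g. ``sign``: Disease -> Symptom), one ``alias``
    attribute ranging over strings, and pairwise disjointness among all seven
    leaf classes (so e.g. Disease ``owl:disjointWith`` Symptom).
    """
    s = SchemaGraph()
    for cid, label in LEAF_CLASSES:
        s.add_class(cid, label)
    s.add_class("Medicine", "Medicine")
    s.add_edge("TCM", SUBCLASS_OF, "Medicine")
    s.add_edge("WesternMedicine", SUBCLASS_OF, "Medicine")
    for rid, dom, ran in RELATIONS:
        s.add_relation(rid, dom, ran)
    s.add_datatype("xsd:string", "string")
    s.add_attribute("alias", "xsd:string", label="Alias")
    leaf_ids = [cid for cid, _ in LEAF_CLASSES]
    for a, b in combinations(leaf_ids, 2):
        s.add_edge(a, DISJOINT_WITH, b)
    return s
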