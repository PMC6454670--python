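"""Portal-dump extraction: heuristic entry mapping, vertical partitioning, D2R.

A vertical portal exposes *navigation pages* (one row per instance of a class,
with a URL-derived identifier) and *detail pages* whose content comes in three
entry shapes: lists, tables and infoboxes. Each entry has a topic sentence
(first line of a list, first row of a table, property label of an infobox)
and a payload of target labels or values.

The pipeline here is the post-processing that follows wrapper induction:

1. :func:`map_entry_to_property` — match an entry's topic sentence against a
   per-property heuristic word set to decide which KB property the entry
   describes;
2. :func:`extract_tables` — rewrite a dump into two-column *property tables*
   (vertical partitioning: one table per property);
3. :func:`d2r_materialize` — translate the tables into a per-portal
   :class:`~dkb.model.DataGraph` (class table rows become ``rdf:type``
   statements by prefixing with the portal namespace; relation table rows
   become instance-to-instance edges when the object label resolves, and
   attribute edges to a value vertex otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    RDF_TYPE,
    DataGraph,
    SchemaGraph,
    normalize_label,
)

ENTRY_KINDS = ("list", "table", "infobox")

#: reserved property-table names (not schema properties)
CLASS_TABLE = "rdf:type"
LABEL_TABLE = "label"


@dataclass(frozen=True)
class Entry:
    """One extraction entry from a detail page."""

    kind: str  # list | table | infobox
    topic: str  # topic sentence / property label
    payload: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ENTRY_KINDS:
            raise ValueError(f"entry kind must be one of {ENTRY_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class NavRow:
    """One navigation-page row: identifier, display label, declared class."""

    identifier: str
    label: str
    class_label: str


@dataclass
class PortalDump:
    """Semi-structured records of one portal, keyed by URL identifier."""

    source: str
    navigation: list[NavRow]
    details: dict[str, list[Entry]] = field(default_factory=dict)

    def check(self) -> None:
        """Raise ``ValueError`` on an invariant breach."""
        idents = [r.identifier for r in self.navigation]
        if len(idents) != len(set(idents)):
            raise ValueError(f"duplicate identifiers in navigation of {self.source!r}")
        known = set(idents)
        stray = set(self.details) - known
        if stray:
            raise ValueError(
                f"detail records without navigation rows in {self.source!r}: "
                f"{sorted(stray)[:5]}"
            )


class HeuristicLexicon:
    """Per-property heuristic word sets S_r with a total priority order.

    An entry's topic sentence is assigned to the highest-priority property
    one of whose words occurs in the sentence (substring containment after
    whitespace/case normalization).
    """

    def __init__(self, words: dict[str, set[str]], priority: list[str] | None = None):
        if not words:
            raise ValueError("lexicon must be non-empty")
        for prop, ws in words.items():
            if not ws:
                raise ValueError(f"empty heuristic word set for {prop!r}")
        self.words = {p: frozenset(ws) for p, ws in words.items()}
        self.priority = list(priority) if priority is not None else sorted(words)
        if sorted(self.priority) != sorted(self.words):
            raise ValueError("priority order must cover exactly the lexicon keys")

    def __iter__(self):
        return iter(self.priority)


def default_lexicon() -> HeuristicLexicon:
    """Heuristic words for the shipped schema's ten relations plus Alias."""
    words = {
        "sign": {"sign", "symptom", "clinical manifestation"},
        "complication": {"complication"},
        "causes": {"cause", "etiology"},
        "risk_factor": {"risk factor", "predisposing"},
        "related_disease": {"related disease", "similar disease"},
        "treated_by_wm": {"western medicine", "drug therapy", "medication"},
        "treated_by_tcm": {"chinese medicine", "tcm", "herbal"},
        "checked_by_exam": {"examination", "laboratory test", "checkup"},
        "belongs_to_dept": {"department", "outpatient"},
        "located_in_body": {"body part", "anatomic site", "affected area"},
        "alias": {"alias", "other name", "also known as"},
    }
    order = [
        "risk_factor", "related_disease", "treated_by_wm", "treated_by_tcm",
        "checked_by_exam", "belongs_to_dept", "located_in_body",
        "complication", "causes", "sign", "alias",
    ]
    return HeuristicLexicon(words, order)


class PropertyTable:
    """Two-column table for exactly one property (vertical partitioning).

    Rows are (subject identifier, object value); fully duplicated rows are
    dropped on append, first occurrence wins.
    """

    def __init__(self, name: str, rows: list[tuple[str, str]] | None = None):
        self.name = name
        self.rows: list[tuple[str, str]] = []
        self._seen: set[tuple[str, str]] = set()
        for s, o in rows or []:
            self.append(s, o)

    def append(self, subject: str, obj: str) -> bool:
        """Add a row; returns False if it was a duplicate."""
        row = (subject, obj)
        if row in self._seen:
            return False
        self._seen.add(row)
        self.rows.append(row)
        return True

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return (isinstance(other, PropertyTable)
                and self.name == other.name
                and sorted(self.rows) == sorted(other.rows))

    def __repr__(self) -> str:
        return f"PropertyTable({self.name!r}, {len(self.rows)} rows)"


def map_entry_to_property(topic_sentence: str, lexicon: HeuristicLexicon) -> str | None:
    """Assign a topic sentence to the highest-priority property whose word
    set has a hit in the sentence; ``None`` when nothing hits.

    A hit is substring containment of the normalized heuristic word in the
    normalized sentence (e.g. "Common Complications" hits "complication").
    """
    sentence = normalize_label(topic_sentence)
    if not sentence:
        return None
    for prop in lexicon.priority:
        for word in sorted(lexicon.words[prop]):
            if normalize_label(word) in sentence:
                return prop
    return None


@dataclass
class ExtractionResult:
    """Vertically-partitioned tables for one dump, plus skip counters."""

    class_table: PropertyTable
    label_table: PropertyTable
    property_tables: list[PropertyTable]
    unmapped_entries: int = 0
    empty_values: int = 0

    @property
    def relation_tables(self) -> list[PropertyTable]:
        return self.property_tables


def extract_tables(dump: PortalDump, lexicon: HeuristicLexicon) -> ExtractionResult:
    """Rewrite a portal dump into two-column property tables.

    The class table gets one row per navigation row (identifier -> declared
    class label) and the label table one row per navigation row (identifier
    -> display label). Every detail entry whose topic sentence maps to a
    property contributes one row per payload element to that property's
    table; unmapped entries and empty payload values are counted and skipped.
    """
    dump.check()
    class_table = PropertyTable(CLASS_TABLE)
    label_table = PropertyTable(LABEL_TABLE)
    for row in dump.navigation:
        class_table.append(row.identifier, row.class_label)
        label_table.append(row.identifier, row.label)

    tables: dict[str, PropertyTable] = {}
    unmapped = 0
    empty = 0
    for identifier, entries in dump.details.items():
        for entry in entries:
            prop = map_entry_to_property(entry.topic, lexicon)
            if prop is None:
                unmapped += 1
                continue
            table = tables.setdefault(prop, PropertyTable(prop))
            for value in entry.payload:
                if not value.strip():
                    empty += 1
                    continue
                table.append(identifier, value)
    ordered = [tables[name] for name in sorted(tables)]
    return ExtractionResult(class_table, label_table, ordered, unmapped, empty)


@dataclass
class D2RResult:
    graph: DataGraph
    rejects: list[tuple[str, str, str, str]]  # (table, subject, object, reason)


def instance_uri(namespace: str, identifier: str) -> str:
    return namespace + identifier


def d2r_materialize(
    class_table: PropertyTable,
    relation_tables: list[PropertyTable],
    schema: SchemaGraph,
    namespace: str,
    label_table: PropertyTable | None = None,
    source: str | None = None,
) -> D2RResult:
    """Translate property tables into a per-portal data graph.

    One instance vertex per class-table subject with URI ``namespace +
    identifier``; one ``rdf:type`` edge per class-table row whose declared
    class label resolves against the schema (unresolvable rows are
    quarantined in ``rejects`` and the graph is still produced). Relation
    rows whose object matches a known instance label in the same portal
    become instance-to-instance edges; unresolved objects become attribute
    edges to a fresh value vertex, which keeps the Def-1 edge-kind
    restrictions satisfiable without inventing dangling instances.
    """
    labels: dict[str, str] = {}
    if label_table is not None:
        for ident, label in label_table.rows:
            labels.setdefault(ident, label)

    graph = DataGraph()
    rejects: list[tuple[str, str, str, str]] = []

    for ident, class_label in class_table.rows:
        uri = instance_uri(namespace, ident)
        graph.add_instance(uri, labels.get(ident, ident), source)
        cls = schema.class_by_label(class_label)
        if cls is None:
            rejects.append((class_table.name, ident, class_label, "unknown class label"))
            continue
        graph.add_edge(uri, RDF_TYPE, cls)

    # exact normalized-label match within this portal
    by_label: dict[str, str] = {}
    for v in graph.instances():
        by_label.setdefault(normalize_label(v.label), v.id)

    relations = schema.relations()
    attributes = schema.attributes()
    for table in relation_tables:
        prop = table.name
        if prop not in relations and prop not in attributes:
            for subj, obj in table.rows:
                rejects.append((prop, subj, obj, "unknown property"))
            continue
        for subj, obj in table.rows:
            s_uri = instance_uri(namespace, subj)
            if s_uri not in graph.vertices:
                # subject never appeared on a navigation page
                graph.add_instance(s_uri, labels.get(subj, subj), source)
            if prop in relations:
                target = by_label.get(normalize_label(obj))
                if target is not None:
                    graph.add_edge(s_uri, prop, target)
                    continue
            vid = graph.add_value(obj)
            graph.add_edge(s_uri, prop, vid)
    return D2RResult(graph, rejects)


def repartition(
    graph: DataGraph, namespace: str, schema: SchemaGraph
) -> tuple[PropertyTable, PropertyTable, list[PropertyTable]]:
    """Rewrite a materialized graph back into two-column property tables.

    Inverse of :func:`d2r_materialize` up to row order (class labels come
    back canonical). Used to check the vertical-partitioning bijection.
    """
    def local(uri: str) -> str:
        return uri[len(namespace):] if uri.startswith(namespace) else uri

    class_table = PropertyTable(CLASS_TABLE)
    label_table = PropertyTable(LABEL_TABLE)
    tables: dict[str, PropertyTable] = {}
    for v in sorted(graph.instances(), key=lambda v: v.id):
        ident = local(v.id)
        for cls in sorted(graph.types_of(v.id)):
            class_table.append(ident, schema.vertices[cls].label)
        label_table.append(ident, v.label)
    for s, p, o in sorted(graph.edges):
        if p == RDF_TYPE:
            continue
        table = tables.setdefault(p, PropertyTable(p))
        target = graph.vertices.get(o)
        obj = target.label if target is not None else o
        table.append(local(s), obj)
    return class_table, label_table, [tables[n] for n in sorted(tables)]
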