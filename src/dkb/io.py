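"""Readers and writers for the package's on-disk formats.

Knowledge graphs serialize to Turtle (``.ttl``) and N-Triples (``.nt``)
through rdflib; property tables, mapping/conflict reports and violations go
to headered TSV; portal dumps are JSON-lines (one record per identifier);
everything is UTF-8.

Data-graph RDF layout: instance vertices keep their ``kb://`` URIs, vertex
labels become ``rdfs:label`` literals, source tags become ``dkb:source``
literals, class/property ids live under the ``kb://schema/`` namespace, and
value vertices are written as plain literals (their deterministic
``value:...`` ids are re-derived on read, so a write/read round trip
preserves the (s, p, o) edge set exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from rdflib import Graph as RDFGraph
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS, OWL

from .extraction import Entry, NavRow, PortalDump, PropertyTable
from .fusion import CodeEntry, MappingAssertion, ReferenceCodeList
from .model import (
    DISJOINT_WITH,
    DOMAIN,
    RANGE,
    RDF_TYPE,
    SUBCLASS_OF,
    DataGraph,
    SchemaGraph,
    Violation,
)

SCHEMA_NS = "kb://schema/"
DKB_NS = "kb://meta/"

_SOURCE = URIRef(DKB_NS + "source")
_KIND = URIRef(DKB_NS + "kind")

_SCHEMA_EDGE_IRIS = {
    DOMAIN: RDFS.domain,
    RANGE: RDFS.range,
    SUBCLASS_OF: RDFS.subClassOf,
    DISJOINT_WITH: OWL.disjointWith,
}
_SCHEMA_EDGE_LABELS = {v: k for k, v in _SCHEMA_EDGE_IRIS.items()}


def _fmt(path: Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".ttl":
        return "turtle"
    if suffix == ".nt":
        return "nt"
    raise ValueError(f"unsupported graph format {suffix!r} (use .ttl or .nt)")


def _schema_iri(local: str) -> URIRef:
    return URIRef(SCHEMA_NS + local)


def _local(iri: URIRef) -> str:
    return str(iri)[len(SCHEMA_NS):]


# ---------------------------------------------------------------------------
# data graphs


def data_graph_to_rdflib(g: DataGraph) -> RDFGraph:
    rg = RDFGraph()
    rg.bind("kbs", SCHEMA_NS)
    rg.bind("dkb", DKB_NS)
    for v in g.vertices.values():
        if v.kind != "I":
            continue
        node = URIRef(v.id)
        rg.add((node, RDFS.label, Literal(v.label)))
        if v.source is not None:
            rg.add((node, _SOURCE, Literal(v.source)))
    for s, p, o in g.edges:
        subj = URIRef(s)
        if p == RDF_TYPE:
            rg.add((subj, RDF.type, _schema_iri(o)))
            continue
        target = g.vertices.get(o)
        if target is not None and target.kind == "V":
            rg.add((subj, _schema_iri(p), Literal(target.label)))
        else:
            rg.add((subj, _schema_iri(p), URIRef(o)))
    return rg


def rdflib_to_data_graph(rg: RDFGraph) -> DataGraph:
    g = DataGraph()
    labels: dict[str, str] = {}
    sources: dict[str, str] = {}
    plain_edges = []
    subjects = set()
    for s, p, o in rg:
        sid = str(s)
        subjects.add(sid)
        if p == RDFS.label:
            labels[sid] = str(o)
        elif p == _SOURCE:
            sources[sid] = str(o)
        elif p == RDF.type:
            plain_edges.append((sid, RDF_TYPE, _local(o)))
        elif str(p).startswith(SCHEMA_NS):
            plain_edges.append((sid, _local(p), o))
        else:
            raise ValueError(f"unrecognized predicate {p} in serialized graph")
    referenced_uris = {o for (_, p, o) in plain_edges
                       if p != RDF_TYPE and isinstance(o, URIRef)}
    for sid in sorted(subjects | {str(u) for u in referenced_uris}):
        g.add_instance(sid, labels.get(sid, sid), sources.get(sid))
    for sid, p, o in plain_edges:
        if p == RDF_TYPE:
            g.add_edge(sid, p, o)
        elif isinstance(o, URIRef):
            g.add_edge(sid, p, str(o))
        else:
            vid = g.add_value(str(o))
            g.add_edge(sid, p, vid)
    return g


def write_data_graph(g: DataGraph, path: str | Path) -> None:
    path = Path(path)
    data_graph_to_rdflib(g).serialize(destination=str(path),
                                      format=_fmt(path), encoding="utf-8")


def read_data_graph(path: str | Path) -> DataGraph:
    path = Path(path)
    rg = RDFGraph()
    rg.parse(str(path), format=_fmt(path))
    return rdflib_to_data_graph(rg)


# ---------------------------------------------------------------------------
# schema graphs


def write_schema(schema: SchemaGraph, path: str | Path) -> None:
    path = Path(path)
    rg = RDFGraph()
    rg.bind("kbs", SCHEMA_NS)
    rg.bind("dkb", DKB_NS)
    for v in schema.vertices.values():
        node = _schema_iri(v.id)
        rg.add((node, _KIND, Literal(v.kind)))
        rg.add((node, RDFS.label, Literal(v.label)))
    for s, lab, t in schema.edges:
        rg.add((_schema_iri(s), _SCHEMA_EDGE_IRIS[lab], _schema_iri(t)))
    rg.serialize(destination=str(path), format=_fmt(path), encoding="utf-8")


def read_schema(path: str | Path) -> SchemaGraph:
    path = Path(path)
    rg = RDFGraph()
    rg.parse(str(path), format=_fmt(path))
    schema = SchemaGraph()
    labels: dict[str, str] = {}
    kinds: dict[str, str] = {}
    edges = []
    for s, p, o in rg:
        if p == _KIND:
            kinds[_local(s)] = str(o)
        elif p == RDFS.label:
            labels[_local(s)] = str(o)
        elif p in _SCHEMA_EDGE_LABELS:
            edges.append((_local(s), _SCHEMA_EDGE_LABELS[p], _local(o)))
        else:
            raise ValueError(f"unrecognized predicate {p} in serialized schema")
    for local, kind in sorted(kinds.items()):
        schema.add_vertex(local, kind, labels.get(local, local))
    for s, lab, t in edges:
        schema.add_edge(s, lab, t)
    return schema


# ---------------------------------------------------------------------------
# TSV tables


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    df = pd.DataFrame(table.rows, columns=["subject", table.name])
    df.to_csv(path, sep="\t", index=False)


def read_property_table(path: str | Path) -> PropertyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df.columns) != 2:
        raise ValueError(f"property table must have exactly two columns: {path}")
    name = df.columns[1]
    return PropertyTable(name, list(df.itertuples(index=False, name=None)))


def write_violations(violations: list[Violation], path: str | Path) -> None:
    rows = [(v.rule, " ".join(map(str, v.subject)), v.message) for v in violations]
    pd.DataFrame(rows, columns=["rule", "subject", "detail"]).to_csv(
        path, sep="\t", index=False)


def write_mappings(mappings: list[MappingAssertion], path: str | Path) -> None:
    rows = [(m.v1, m.v2, m.score) for m in mappings]
    pd.DataFrame(rows, columns=["v1", "v2", "score"]).to_csv(
        path, sep="\t", index=False)


def read_mappings(path: str | Path) -> list[MappingAssertion]:
    df = pd.read_csv(path, sep="\t", dtype={"v1": str, "v2": str, "score": float})
    return [MappingAssertion(r.v1, r.v2, float(r.score))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# reference code lists


def write_code_list(codes: ReferenceCodeList, path: str | Path) -> None:
    rows = [(e.code, e.label, "|".join(e.aliases)) for e in codes.entries]
    pd.DataFrame(rows, columns=["code", "label", "aliases"]).to_csv(
        path, sep="\t", index=False)


def read_code_list(path: str | Path) -> ReferenceCodeList:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = [
        CodeEntry(r.code, r.label, tuple(a for a in r.aliases.split("|") if a))
        for r in df.itertuples(index=False)
    ]
    return ReferenceCodeList(entries)


# ---------------------------------------------------------------------------
# portal dumps (JSON lines, one record per identifier)


def write_portal_dump(dump: PortalDump, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        header = {"source": dump.source}
        fh.write(json.dumps(header, ensure_ascii=False) + "\n")
        details = dump.details
        for row in dump.navigation:
            record = {
                "identifier": row.identifier,
                "label": row.label,
                "class": row.class_label,
                "entries": [
                    {"kind": e.kind, "topic": e.topic, "payload": list(e.payload)}
                    for e in details.get(row.identifier, [])
                ],
            }
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_portal_dump(path: str | Path) -> PortalDump:
    navigation: list[NavRow] = []
    details: dict[str, list[Entry]] = {}
    source = Path(path).stem
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
            if "source" in record and "identifier" not in record:
                source = record["source"]
                continue
            navigation.append(NavRow(record["identifier"], record["label"],
                                     record["class"]))
            entries = [
                Entry(e["kind"], e["topic"], tuple(e["payload"]))
                for e in record.get("entries", [])
            ]
            if entries:
                details[record["identifier"]] = entries
    return PortalDump(source, navigation, details)


# ---------------------------------------------------------------------------
# seeds


def write_seeds(seeds: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(seeds) + "\n", encoding="utf-8")


def read_seeds(path: str | Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
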