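"""End-to-end workflow: extract -> D2R -> cleanse -> match -> fuse -> EM.

Library counterpart of the ``dkb run`` command. Each stage failure is
wrapped in :class:`StageError` carrying the stage name, so a broken corpus
aborts with context instead of a deep traceback.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from . import io as kbio
from .em import EMConfig, TraceRow, extract_topic_kb, iteration_trace
from .extraction import default_lexicon, d2r_materialize, extract_tables
from .fusion import (
    IntegratedDataGraph,
    MatchConfig,
    cleanse_classes,
    fuse,
    match_instances,
)
from .model import DataGraph, SchemaGraph, default_diabetes_schema, normalize_label, validate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    match: MatchConfig = field(default_factory=MatchConfig)
    em: EMConfig = field(default_factory=EMConfig)
    code_list_coverage: float = 0.6  # used by `dkb simulate`
    n_seeds: int = 6


@dataclass
class PipelineResult:
    portal_graphs: dict[str, DataGraph]
    fused: DataGraph
    dkb: DataGraph
    trace: list[TraceRow]
    stats: list[tuple[str, int, int]]  # (name, instances, edges)
    cleansing_report: object
    mappings: list
    seeds: list[str]


def _guard(stage: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(stage, str(exc)) from exc
            return False

    return _Ctx()


def resolve_seeds(graph: DataGraph, seed_labels: list[str]) -> list[str]:
    """Resolve seed labels (or URIs) to instance ids in a graph.

    Matches the vertex label or any value attached through an ``alias``
    attribute edge, after normalization. Raises ``KeyError`` listing the
    seeds that cannot be resolved.
    """
    by_name: dict[str, str] = {}
    for v in sorted(graph.instances(), key=lambda v: v.id):
        by_name.setdefault(normalize_label(v.label), v.id)
    for s, p, o in sorted(graph.edges):
        if p == "alias":
            target = graph.vertices.get(o)
            if target is not None and target.kind == "V" and s in graph.vertices:
                by_name.setdefault(normalize_label(target.label), s)
    resolved, missing = [], []
    for seed in seed_labels:
        if seed in graph.vertices:
            resolved.append(seed)
        elif normalize_label(seed) in by_name:
            resolved.append(by_name[normalize_label(seed)])
        else:
            missing.append(seed)
    if missing:
        raise KeyError(f"seeds not found in the knowledge base: {missing}")
    return resolved


def portal_graphs_from_dumps(
    dumps,
    schema: SchemaGraph | None = None,
    lexicon=None,
) -> dict[str, DataGraph]:
    """Extract + D2R-materialize a list of portal dumps into per-source graphs."""
    schema = schema or default_diabetes_schema()
    lexicon = lexicon or default_lexicon()
    out: dict[str, DataGraph] = {}
    for dump in dumps:
        tables = extract_tables(dump, lexicon)
        result = d2r_materialize(
            tables.class_table,
            tables.property_tables,
            schema,
            namespace=f"kb://{dump.source}/",
            label_table=tables.label_table,
            source=dump.source,
        )
        out[dump.source] = result.graph
    return out


def run_pipeline(
    corpus_dir: str | Path,
    config: PipelineConfig | None = None,
    schema: SchemaGraph | None = None,
) -> PipelineResult:
    """Run the full construction workflow over a corpus directory.

    Expects per-portal ``*.jsonl`` dumps, a ``codes.tsv`` reference list and
    a ``seeds.txt`` file of topic seed labels (as written by ``dkb
    simulate``).
    """
    corpus_dir = Path(corpus_dir)
    cfg = config or PipelineConfig()
    schema = schema or default_diabetes_schema()
    lexicon = default_lexicon()

    with _guard("extract"):
        dump_paths = sorted(corpus_dir.glob("*.jsonl"))
        if not dump_paths:
            raise FileNotFoundError(f"no portal dumps (*.jsonl) in {corpus_dir}")
        dumps = [kbio.read_portal_dump(p) for p in dump_paths]

    with _guard("d2r"):
        portal_graphs = portal_graphs_from_dumps(dumps, schema, lexicon)
        for name, g in sorted(portal_graphs.items()):
            logger.info("portal %s: %d instances, %d edges",
                        name, g.n_instances, len(g.edges))

    with _guard("cleanse"):
        codes_path = corpus_dir / "codes.tsv"
        if not codes_path.exists():
            raise FileNotFoundError(f"missing reference code list {codes_path}")
        codes = kbio.read_code_list(codes_path)
        integrated = IntegratedDataGraph(
            [portal_graphs[k] for k in sorted(portal_graphs)])
        integrated, report = cleanse_classes(integrated, codes, schema)

    with _guard("match"):
        mappings = []
        for g1, g2 in combinations(integrated.graphs, 2):
            mappings.extend(match_instances(g1, g2, cfg.match))
        integrated.mappings = mappings

    with _guard("fuse"):
        fused = fuse(integrated, schema)

    with _guard("em"):
        seeds_path = corpus_dir / "seeds.txt"
        if not seeds_path.exists():
            raise FileNotFoundError(f"missing seeds file {seeds_path}")
        seed_ids = resolve_seeds(fused, kbio.read_seeds(seeds_path))
        dkb = extract_topic_kb(fused, seed_ids, cfg.em)
        trace = iteration_trace(fused, seed_ids, cfg.em)

    stats = [
        (name, g.n_instances, len(g.edges))
        for name, g in sorted(portal_graphs.items())
    ]
    stats.append(("Overall KB", fused.n_instances, len(fused.edges)))
    stats.append(("DKB", dkb.n_instances, len(dkb.edges)))

    return PipelineResult(portal_graphs, fused, dkb, trace, stats,
                          report, mappings, seed_ids)


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  schema: SchemaGraph | None = None,
                  manifest_extra: dict | None = None) -> None:
    """Materialize pipeline outputs: KBs, reports, trace, stats, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = schema or default_diabetes_schema()

    kbio.write_data_graph(result.fused, out_dir / "overall_kb.ttl")
    kbio.write_data_graph(result.dkb, out_dir / "dkb.ttl")
    kbio.write_schema(schema, out_dir / "schema.ttl")
    kbio.write_mappings(result.mappings, out_dir / "mappings.tsv")
    kbio.write_violations(validate(result.fused, schema),
                          out_dir / "violations.tsv")

    import pandas as pd

    pd.DataFrame(
        [(r.label, ",".join(r.classes), r.winner or "", r.method, r.score)
         for r in result.cleansing_report.resolutions],
        columns=["label", "classes", "winner", "method", "score"],
    ).to_csv(out_dir / "conflicts.tsv", sep="\t", index=False)
    pd.DataFrame(result.trace,
                 columns=["iteration", "centers", "vertices", "edges"]
                 ).to_csv(out_dir / "trace.tsv", sep="\t", index=False)
    pd.DataFrame(result.stats, columns=["source", "instances", "edges"]
                 ).to_csv(out_dir / "stats.tsv", sep="\t", index=False)

    manifest = {
        "stages": ["extract", "d2r", "cleanse", "match", "fuse", "em"],
        "stats": {name: {"instances": i, "edges": e}
                  for name, i, e in result.stats},
        "n_mappings": len(result.mappings),
        "n_conflicts": result.cleansing_report.n_conflicts,
        "seeds": result.seeds,
    }
    manifest.update(manifest_extra or {})
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8")


def config_digest(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode("utf-8")
    ).hexdigest()[:16]
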