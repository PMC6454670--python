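"""Synthetic corpora with planted ground truth for every pipeline stage.

Real portal crawls cannot ship with the package, so tests and experiments run
on generated corpora that mirror the shape of the study setting: a master
typed KB over the seven-class diabetes schema with a dense topic community,
projected into eight portal views with per-portal class-coverage gaps, label
aliases, duplicated instances and class-flip noise dominated by the
disease/symptom confusion.

Everything is driven by one :class:`CorpusConfig` seed: master graph, portal
views and reference code list are reproducible bit-for-bit, and
:class:`GroundTruth` records the planted facts (topic members, duplicate
clusters, true classes, aliases) that the recovery metrics score against.

Edge model: relation edges are directed triples. For every ordered instance
pair whose class pair admits at least one schema relation, one Bernoulli
draw decides whether a triple is present (probability ``p_in`` when both
endpoints are topic members, else ``p_out``), and the relation is drawn
uniformly among the admissible ones. Realized within-topic density over
admissible ordered pairs is therefore binomial around ``p_in``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .extraction import Entry, HeuristicLexicon, NavRow, PortalDump, default_lexicon
from .fusion import CodeEntry, MappingAssertion, ReferenceCodeList
from .model import (
    RDF_TYPE,
    DataGraph,
    SchemaGraph,
    default_diabetes_schema,
)

MASTER_NAMESPACE = "kb://master/"

#: the eight portal source tags
PORTALS = (
    "39health", "99health", "fhhealth", "familydoctor",
    "globalhospital", "pcbaby", "jianke", "120ask",
)

ALL7 = frozenset(c for c, _, in (
    ("Disease", 0), ("Symptom", 0), ("WesternMedicine", 0), ("TCM", 0),
    ("Examination", 0), ("Department", 0), ("BodyStructure", 0),
))

#: per-portal class coverage: a synthetic stand-in mirroring the emulated
#: portal ecosystem, where every portal carries diseases, symptoms,
#: departments and body structures, two portals carry no medicine data and
#: only some describe examinations (per-portal class counts 7,5,6,6,4,6,7,7).
DEFAULT_COVERAGE: dict[str, frozenset] = {
    "39health": ALL7,
    "99health": frozenset({"Disease", "Symptom", "Examination", "Department", "BodyStructure"}),
    "fhhealth": frozenset({"Disease", "Symptom", "WesternMedicine", "TCM", "Department", "BodyStructure"}),
    "familydoctor": frozenset({"Disease", "Symptom", "WesternMedicine", "TCM", "Department", "BodyStructure"}),
    "globalhospital": frozenset({"Disease", "Symptom", "Department", "BodyStructure"}),
    "pcbaby": frozenset({"Disease", "Symptom", "WesternMedicine", "TCM", "Department", "BodyStructure"}),
    "jianke": ALL7,
    "120ask": ALL7,
}

DEFAULT_INSTANCES_PER_CLASS = {
    "Disease": 600,
    "Symptom": 300,
    "WesternMedicine": 80,
    "TCM": 80,
    "Examination": 50,
    "Department": 24,
    "BodyStructure": 66,
}

_CLASS_PREFIX = {
    "Disease": "dis", "Symptom": "sym", "WesternMedicine": "wm", "TCM": "tcm",
    "Examination": "exa", "Department": "dep", "BodyStructure": "bod",
}

_SYLLABLES = (
    "ka", "mo", "ri", "ta", "lu", "ne", "si", "vo", "pa", "de",
    "gi", "ru", "fa", "mi", "to", "la", "be", "no", "du", "sa",
)

_TOPIC_TEMPLATES = ("{w}", "common {w}", "{w} overview")
_DISTRACTORS = ("patient stories", "popular articles", "expert q&a")


@dataclass
class CorpusConfig:
    """Study-condition parameters for corpus generation.

    Defaults mirror the emulated setting: 8 portals with per-portal class
    coverage gaps, a dense topic community (p_in = 0.2 inside, p_out = 0.01
    elsewhere), 25% per-portal duplication (so an instance lands in ~2 of
    the 8 portals on average — real multi-portal crawls sum to roughly
    twice as many instance placements as distinct instances), 20% alias
    substitution, 10% class-flip noise of which 90% are disease/symptom
    confusions.
    """

    seed: int = 0
    portals: tuple[str, ...] = PORTALS
    coverage: dict[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE))
    instances_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INSTANCES_PER_CLASS))
    topic_size: int = 80
    p_in: float = 0.2
    p_out: float = 0.01
    duplication_rate: float = 0.25
    alias_rate: float = 0.2
    class_flip_rate: float = 0.1
    disease_symptom_share: float = 0.9
    distractor_rate: float = 0.3
    ensure_topic_connected: bool = True

    def check(self) -> None:
        for name in ("p_in", "p_out", "duplication_rate", "alias_rate",
                     "class_flip_rate", "disease_symptom_share", "distractor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = sum(self.instances_per_class.values())
        if self.topic_size > total:
            raise ValueError(
                f"topic community ({self.topic_size}) larger than population ({total})")
        if self.instances_per_class.get("Disease", 0) < 1:
            raise ValueError("the population needs at least one Disease instance")
        unknown = set(self.coverage) - set(self.portals)
        if unknown:
            raise ValueError(f"coverage for unknown portals: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted facts behind a generated corpus."""

    master: DataGraph
    topic: set[str]  # master instance ids in the topic community
    true_class: dict[str, str]  # master id -> class id
    aliases: dict[str, tuple[str, ...]]  # master id -> alias labels
    duplicates: dict[str, dict[str, str]] = field(default_factory=dict)
    # master id -> {portal: portal URI}
    flipped: set[tuple[str, str]] = field(default_factory=set)
    # (portal, master id) pairs whose declared class was corrupted

    def portal_to_master(self) -> dict[str, str]:
        out = {}
        for mid, placements in self.duplicates.items():
            for uri in placements.values():
                out[uri] = mid
        return out

    def closed_topic(self) -> set[str]:
        """Topic members plus their relation neighbors in the master graph."""
        out = set(self.topic)
        for s, p, o in self.master.relation_edges():
            if s in self.topic:
                out.add(o)
            if o in self.topic:
                out.add(s)
        return out


def _fresh_label(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        k = int(rng.integers(3, 5))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(k))
        if word not in used:
            used.add(word)
            return word


def _make_alias(rng: np.random.Generator, label: str, used: set[str]) -> str:
    # abbreviation or suffix transform: similar but not identical strings
    candidates = (label[: max(3, 2 * len(label) // 3)],
                  label + str(rng.choice(_SYLLABLES)))
    alias = str(candidates[int(rng.integers(2))])
    while alias in used or alias == label:
        alias = alias + str(rng.choice(_SYLLABLES))
    used.add(alias)
    return alias


def _relation_slots(schema: SchemaGraph) -> dict[tuple[str, str], list[str]]:
    """(domain class, range class) -> admissible relations."""
    slots: dict[tuple[str, str], list[str]] = defaultdict(list)
    for rid in sorted(schema.relations()):
        dom, ran = schema.domain_of(rid), schema.range_of(rid)
        if dom is not None and ran is not None:
            slots[(dom, ran)].append(rid)
    return dict(slots)


def generate_master(
    config: CorpusConfig, schema: SchemaGraph | None = None
) -> tuple[DataGraph, GroundTruth]:
    """Generate the master KB and its ground truth.

    Instances are allocated per class with unique pseudo-labels and one or
    two aliases each; the topic community is sampled with Disease instances
    weighted 3:1 (topic neighborhoods in a disease-centric KB are
    disease-heavy). Relation triples are drawn per the module's directed
    Bernoulli model, always respecting relation domain/range, so the master
    validates cleanly. With ``ensure_topic_connected`` (default) the topic
    community is patched into a single connected component, as a topic
    community is by definition.
    """
    config.check()
    schema = schema or default_diabetes_schema()
    rng = np.random.default_rng([config.seed, 0])

    graph = DataGraph()
    truth_class: dict[str, str] = {}
    aliases: dict[str, tuple[str, ...]] = {}
    used: set[str] = set()
    ids_by_class: dict[str, list[str]] = {}
    for cls in sorted(config.instances_per_class):
        prefix = _CLASS_PREFIX.get(cls, cls[:3].lower())
        ids = []
        for i in range(config.instances_per_class[cls]):
            mid = f"{MASTER_NAMESPACE}{prefix}{i:04d}"
            label = _fresh_label(rng, used)
            graph.add_instance(mid, label, "master")
            graph.add_edge(mid, RDF_TYPE, cls)
            truth_class[mid] = cls
            n_alias = 1 + int(rng.random() < 0.3)
            aliases[mid] = tuple(_make_alias(rng, label, used) for _ in range(n_alias))
            ids.append(mid)
        ids_by_class[cls] = ids

    all_ids = [i for c in sorted(ids_by_class) for i in ids_by_class[c]]
    weights = np.array([3.0 if truth_class[i] == "Disease" else 1.0 for i in all_ids])
    topic = set(rng.choice(all_ids, size=config.topic_size, replace=False,
                           p=weights / weights.sum()).tolist())

    slots = _relation_slots(schema)
    is_topic = {i: (i in topic) for i in all_ids}
    for (dom, ran), rels in sorted(slots.items()):
        subjects = ids_by_class.get(dom, [])
        objects = ids_by_class.get(ran, [])
        if not subjects or not objects:
            continue
        t_s = np.array([is_topic[s] for s in subjects])
        t_o = np.array([is_topic[o] for o in objects])
        probs = np.where(np.outer(t_s, t_o), config.p_in, config.p_out)
        hits = rng.random(probs.shape) < probs
        if dom == ran:
            np.fill_diagonal(hits, False)
        si, oi = np.nonzero(hits)
        ridx = rng.integers(0, len(rels), size=len(si))
        for a, b, r in zip(si, oi, ridx):
            graph.add_edge(subjects[a], rels[r], objects[b])

    if config.ensure_topic_connected and len(topic) > 1:
        _connect_topic(graph, topic, truth_class, slots, rng)

    truth = GroundTruth(graph, topic, truth_class, aliases)
    return graph, truth


def _connect_topic(graph: DataGraph, topic: set[str], truth_class: dict[str, str],
                   slots: dict[tuple[str, str], list[str]], rng: np.random.Generator) -> None:
    """Patch the topic community into one connected component."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(topic)
    for s, p, o in graph.relation_edges():
        if s in topic and o in topic:
            G.add_edge(s, o)
    comps = sorted(nx.connected_components(G), key=len, reverse=True)
    main = comps[0]
    diseases_main = sorted(i for i in main if truth_class[i] == "Disease")
    for comp in comps[1:]:
        u = sorted(comp)[int(rng.integers(len(comp)))]
        if truth_class[u] == "Disease":
            v = sorted(main)[int(rng.integers(len(main)))]
            rels = slots.get(("Disease", truth_class[v]))
            if rels:
                graph.add_edge(u, rels[int(rng.integers(len(rels)))], v)
                main |= comp
                continue
        if diseases_main:
            d = diseases_main[int(rng.integers(len(diseases_main)))]
            rels = slots.get(("Disease", truth_class[u]))
            if rels:
                graph.add_edge(d, rels[int(rng.integers(len(rels)))], u)
                main |= comp
                continue
        raise ValueError("cannot connect topic community under the schema")


def generate_portal_views(
    master: DataGraph,
    truth: GroundTruth,
    config: CorpusConfig,
    lexicon: HeuristicLexicon | None = None,
    schema: SchemaGraph | None = None,
) -> list[PortalDump]:
    """Project the master KB into noisy per-portal dumps.

    Each portal sees only its covered classes; a covered instance lands in a
    portal with probability ``duplication_rate``. Its display label is
    replaced by an alias at ``alias_rate`` and its declared class flipped at
    ``class_flip_rate`` — disease/symptom instances swap classes with
    probability ``disease_symptom_share``, everything else flips to a random
    other covered class. Detail records re-emit the master out-edges as
    list/table/infobox entries with heuristic-word topic sentences plus
    distractor entries, and an Alias infobox carries the names the portal
    did not use (so alias substitution stays recoverable by matching).

    Populates ``truth.duplicates`` and ``truth.flipped`` as a side effect.
    """
    lexicon = lexicon or default_lexicon()
    schema = schema or default_diabetes_schema()
    rng = np.random.default_rng([config.seed, 1])
    class_label = {c: schema.vertices[c].label for c in schema.classes()}
    leaf = sorted(schema.leaf_classes())

    out_edges: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for s, p, o in sorted(master.relation_edges()):
        out_edges[s][p].append(o)

    truth.duplicates = {mid: {} for mid in truth.true_class}
    truth.flipped = set()
    dumps = []
    for portal in config.portals:
        covered = config.coverage.get(portal, frozenset(leaf))
        nav: list[NavRow] = []
        details: dict[str, list[Entry]] = {}
        for v in sorted(master.instances(), key=lambda v: v.id):
            mid = v.id
            cls = truth.true_class[mid]
            if cls not in covered or rng.random() > config.duplication_rate:
                continue
            ident = mid[len(MASTER_NAMESPACE):]
            truth.duplicates[mid][portal] = f"kb://{portal}/{ident}"

            use_alias = truth.aliases[mid] and rng.random() < config.alias_rate
            label = truth.aliases[mid][0] if use_alias else v.label

            declared = cls
            if rng.random() < config.class_flip_rate:
                if cls in ("Disease", "Symptom") and rng.random() < config.disease_symptom_share:
                    declared = "Symptom" if cls == "Disease" else "Disease"
                else:
                    others = [c for c in leaf if c != cls and c in covered]
                    if others:
                        declared = others[int(rng.integers(len(others)))]
                if declared != cls:
                    truth.flipped.add((portal, mid))
            nav.append(NavRow(ident, label, class_label[declared]))

            entries: list[Entry] = []
            for rel in sorted(out_edges.get(mid, ())):
                words = sorted(lexicon.words[rel])
                template = _TOPIC_TEMPLATES[int(rng.integers(len(_TOPIC_TEMPLATES)))]
                topic_sentence = template.format(w=words[int(rng.integers(len(words)))])
                kind = ("list", "table", "infobox")[int(rng.integers(3))]
                payload = tuple(master.vertices[o].label
                                for o in out_edges[mid][rel])
                entries.append(Entry(kind, topic_sentence, payload))
            other_names = ((v.label,) + tuple(truth.aliases[mid][1:])
                           if use_alias else truth.aliases[mid])
            if other_names:
                alias_words = sorted(lexicon.words["alias"])
                entries.append(Entry(
                    "infobox",
                    alias_words[int(rng.integers(len(alias_words)))],
                    other_names,
                ))
            if rng.random() < config.distractor_rate:
                entries.append(Entry(
                    "list",
                    _DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))],
                    ("filler-" + str(int(rng.integers(1000))),),
                ))
            details[ident] = entries
        dumps.append(PortalDump(portal, nav, details))
    return dumps


def generate_code_list(
    truth: GroundTruth, coverage: float, seed: int = 0
) -> ReferenceCodeList:
    """A reference disease code list covering a fraction of the true diseases.

    Includes ``coverage`` of the planted Disease labels (with their aliases)
    and nothing else, emulating the partial coverage of an ICD-style list
    over colloquial portal vocabulary.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must lie in [0, 1], got {coverage}")
    rng = np.random.default_rng([seed, 2])
    diseases = sorted(m for m, c in truth.true_class.items() if c == "Disease")
    k = int(round(coverage * len(diseases)))
    chosen = sorted(rng.choice(diseases, size=k, replace=False).tolist()) if k else []
    entries = [
        CodeEntry(f"E{i:05d}", truth.master.vertices[mid].label,
                  truth.aliases.get(mid, ()))
        for i, mid in enumerate(chosen)
    ]
    return ReferenceCodeList(entries)


# ---------------------------------------------------------------------------
# recovery metrics


def _prf(predicted: set, actual: set) -> dict[str, float]:
    tp = len(predicted & actual)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(actual) if actual else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "n_predicted": len(predicted), "n_actual": len(actual)}


def _resolve_master(ids: set[str], truth: GroundTruth) -> set[str]:
    reverse = truth.portal_to_master()
    out = set()
    for i in ids:
        if i in truth.true_class:
            out.add(i)
        elif i in reverse:
            out.add(reverse[i])
        else:
            raise KeyError(f"result references unknown instance id {i!r}")
    return out


def topic_metrics(result: DataGraph | set, truth: GroundTruth,
                  closed: bool = False) -> dict[str, float]:
    """Precision/recall/F1 of topic membership against the planted community
    (or its closed neighborhood with ``closed=True``). Accepts a data graph
    or a bare id set; portal/fused URIs are resolved to master instances."""
    ids = result.instance_ids() if isinstance(result, DataGraph) else set(result)
    predicted = _resolve_master(ids, truth)
    actual = truth.closed_topic() if closed else set(truth.topic)
    return _prf(predicted, actual)


def matching_metrics(mappings: list[MappingAssertion],
                     truth: GroundTruth) -> dict[str, float]:
    """Precision/recall/F1 of matched pairs against planted duplicate
    clusters (all unordered cross-portal pairs within a cluster)."""
    reverse = truth.portal_to_master()
    predicted = set()
    for m in mappings:
        if m.v1 not in reverse or m.v2 not in reverse:
            raise KeyError(f"mapping references unknown instance: {m}")
        predicted.add(m.pair())
    actual = set()
    for mid, placements in truth.duplicates.items():
        uris = sorted(placements.values())
        for i, a in enumerate(uris):
            for b in uris[i + 1:]:
                actual.add(frozenset((a, b)))
    return _prf(predicted, actual)


def cleansing_metrics(assignments: dict[str, str],
                      truth: GroundTruth) -> dict[str, float]:
    """Accuracy of per-portal class assignments against planted true classes.

    ``assignments`` maps portal URIs to class ids. Reports overall accuracy
    and the restoration rate over the instances whose declared class was
    flipped by the generator.
    """
    reverse = truth.portal_to_master()
    uri_by_placement = {
        uri: (portal, mid)
        for mid, placements in truth.duplicates.items()
        for portal, uri in placements.items()
    }
    correct = 0
    flipped_total = 0
    flipped_correct = 0
    for uri, cls in assignments.items():
        if uri not in reverse:
            raise KeyError(f"assignment references unknown instance id {uri!r}")
        mid = reverse[uri]
        ok = cls == truth.true_class[mid]
        correct += ok
        if uri_by_placement[uri] in truth.flipped:
            flipped_total += 1
            flipped_correct += ok
    n = len(assignments)
    return {
        "accuracy": correct / n if n else 0.0,
        "flipped_accuracy": flipped_correct / flipped_total if flipped_total else 0.0,
        "n": n,
        "n_flipped": flipped_total,
    }


def score_recovery(result, truth: GroundTruth) -> dict:
    """Dispatch to the appropriate planted-truth metric.

    * DataGraph or id set -> topic-membership precision/recall/F1;
    * list of MappingAssertion -> matching precision/recall/F1;
    * dict of uri -> class -> cleansing accuracy.
    """
    if isinstance(result, DataGraph) or isinstance(result, (set, frozenset)):
        return {"topic": topic_metrics(result, truth)}
    if isinstance(result, dict):
        return {"cleansing": cleansing_metrics(result, truth)}
    if isinstance(result, list):
        return {"matching": matching_metrics(result, truth)}
    raise TypeError(f"cannot score result of type {type(result).__name__}")


def class_assignments(graphs: list[DataGraph]) -> dict[str, str]:
    """Portal URI -> single asserted class (sorted-first on the rare
    multi-typed instance), for feeding :func:`cleansing_metrics`."""
    out = {}
    for g in graphs:
        types = g.type_map()
        for v in g.instances():
            ts = sorted(types.get(v.id, ()))
            if ts:
                out[v.id] = ts[0]
    return out


def planted_partition_config(
    n_topic: int = 150,
    n_background: int = 850,
    p_in: float = 0.2,
    p_out: float = 0.01,
    seed: int = 0,
) -> CorpusConfig:
    """Config realizing an exact planted partition for topic-recovery runs.

    The population is all Disease instances: under the disease-centric
    schema every ordered pair then admits a relation, so the directed
    Bernoulli edge model produces a textbook planted-partition graph
    (a mixed-class population would instead yield hub-structured graphs,
    compatibility being disease-mediated).
    """
    return CorpusConfig(
        seed=seed,
        instances_per_class={"Disease": n_topic + n_background},
        topic_size=n_topic,
        p_in=p_in,
        p_out=p_out,
        ensure_topic_connected=False,
    )
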