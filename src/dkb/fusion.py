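"""Multi-source knowledge fusion: class cleansing, instance matching, merging.

Portal extractions disagree. The dominant error mode is a conflicting class
assignment for the same label across sources — overwhelmingly the
disease/symptom confusion — which breaks the schema's disjointness axioms.
Cleansing resolves such conflicts in two steps with absolute precedence:

1. **Reference-list lookup** — a label that exactly matches a disease code
   list (an ICD-10-style label -> code mapping) is a Disease, full stop.
2. **Voting** — otherwise the class supported by the most source portals
   wins: ``v*_c = argmax_c (1/n) * sum_i 1(v_c, v_ci)`` over the n sources
   describing the label.

After cleansing, instance matching derives cross-source correspondences
``m(v1, v2)`` through the standard five-step process (feature engineering,
candidate selection, similarity computation, aggregation, correspondence
derivation), restricted to instances sharing a class. :func:`fuse` collapses
matched clusters into canonical instances.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations

from .model import (
    RDF_TYPE,
    DataGraph,
    SchemaGraph,
    merge_graphs,
    normalize_label,
)

logger = logging.getLogger(__name__)

try:  # fast C edit distance
    import edlib

    def levenshtein(a: str, b: str) -> int:
        if a == b:
            return 0
        if not a or not b:
            return max(len(a), len(b))
        return edlib.align(a, b)["editDistance"]

except ImportError:  # pragma: no cover - edlib is a hard dependency

    def levenshtein(a: str, b: str) -> int:
        if a == b:
            return 0
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]


def string_similarity(a: str, b: str) -> float:
    """1 - normalized Levenshtein distance, on normalized labels."""
    a, b = normalize_label(a), normalize_label(b)
    if not a and not b:
        return 1.0
    longest = max(len(a), len(b))
    return 1.0 - levenshtein(a, b) / longest


# ---------------------------------------------------------------------------
# reference code list


@dataclass(frozen=True)
class CodeEntry:
    code: str
    label: str
    aliases: tuple[str, ...] = ()


class ReferenceCodeList:
    """Disease classification list: code -> canonical label + aliases.

    Emulates the ICD-10 Chinese-description mapping used as the gold
    standard for separating disease instances. Codes are unique; lookup is
    exact match on the normalized label or any alias.
    """

    def __init__(self, entries: list[CodeEntry]):
        codes = [e.code for e in entries]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate codes in reference list")
        self.entries = list(entries)
        self._terms: set[str] = set()
        for e in entries:
            self._terms.add(normalize_label(e.label))
            self._terms.update(normalize_label(a) for a in e.aliases)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self._terms


def reference_lookup(label: str, codes: ReferenceCodeList) -> str | None:
    """``"Disease"`` iff the label exactly matches a list term, else None."""
    if not label.strip():
        raise ValueError("label must be non-empty")
    return "Disease" if label in codes else None


# ---------------------------------------------------------------------------
# voting


@dataclass
class ClassVote:
    """Per-label vote tally: class -> number of supporting sources."""

    label: str
    tally: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.tally.values())


def vote_class(vote: ClassVote) -> tuple[str, float]:
    """Majority class and its support score n_c / n.

    Deterministic tie-break: a tied Disease wins (the reference list having
    already been exhausted by the caller), otherwise the lexicographically
    smallest class. Raises ``ValueError`` on an empty tally.
    """
    if not vote.tally or vote.n < 1:
        raise ValueError(f"empty tally for label {vote.label!r}")
    best = max(vote.tally.values())
    tied = sorted(c for c, k in vote.tally.items() if k == best)
    winner = "Disease" if "Disease" in tied else tied[0]
    return winner, best / vote.n


# ---------------------------------------------------------------------------
# integrated graph


@dataclass(frozen=True)
class MappingAssertion:
    """Approximate correspondence m(v1, v2) between instances of two sources."""

    v1: str
    v2: str
    score: float

    def pair(self) -> frozenset:
        return frozenset((self.v1, self.v2))


@dataclass
class IntegratedDataGraph:
    """A set of per-source data graphs plus cross-source mappings."""

    graphs: list[DataGraph]
    mappings: list[MappingAssertion] = field(default_factory=list)

    def check(self) -> None:
        ids: set[str] = set()
        for g in self.graphs:
            ids |= g.instance_ids()
        for m in self.mappings:
            if m.v1 not in ids or m.v2 not in ids:
                raise ValueError(f"mapping endpoint missing from member graphs: {m}")


# ---------------------------------------------------------------------------
# class cleansing


@dataclass(frozen=True)
class ConflictResolution:
    label: str
    classes: tuple[str, ...]
    winner: str | None
    method: str  # lookup | vote | tie-break | unresolved
    score: float


@dataclass
class CleansingReport:
    resolutions: list[ConflictResolution] = field(default_factory=list)

    @property
    def n_conflicts(self) -> int:
        return len(self.resolutions)

    @property
    def n_resolved(self) -> int:
        return sum(1 for r in self.resolutions if r.winner is not None)

    @property
    def coverage(self) -> float:
        """Fraction of conflicting labels the strategy could decide."""
        return self.n_resolved / self.n_conflicts if self.n_conflicts else 1.0

    def resolved_labels(self) -> set[str]:
        return {r.label for r in self.resolutions if r.winner is not None}


def _portal_class_of(graph: DataGraph, label_norm: str) -> str | None:
    """The single class a portal asserts for a label.

    Self-conflicting descriptions within one portal are resolved first, by
    majority over that portal's type edges then lexicographically.
    """
    tally: Counter = Counter()
    types = graph.type_map()
    for v in graph.instances():
        if normalize_label(v.label) == label_norm:
            for c in types.get(v.id, ()):
                tally[c] += 1
    if not tally:
        return None
    best = max(tally.values())
    return sorted(c for c, k in tally.items() if k == best)[0]


def cleanse_classes(
    integrated: IntegratedDataGraph,
    codes: ReferenceCodeList,
    schema: SchemaGraph,
    strategy: str = "combined",
) -> tuple[IntegratedDataGraph, CleansingReport]:
    """Resolve conflicting class assignments across the member graphs.

    For every normalized label whose instances carry disjoint classes across
    sources, the winner class is decided by ``strategy``:

    * ``"combined"`` (default) — reference-list lookup first, voting for the
      remainder (the shipped algorithm);
    * ``"lookup-only"`` — conflicts whose label misses the list stay
      unresolved (baseline);
    * ``"vote-only"`` — pure majority voting (baseline).

    All ``rdf:type`` edges of the affected instances are rewritten to the
    winner, so resolved labels cannot breach disjointness afterwards; the
    pass is idempotent. Unresolved conflicts are reported, never dropped.
    """
    if strategy not in ("combined", "lookup-only", "vote-only"):
        raise ValueError(f"unknown strategy {strategy!r}")

    graphs = [g.copy() for g in integrated.graphs]
    report = CleansingReport()

    # label -> per-source class
    label_classes: dict[str, dict[int, str]] = defaultdict(dict)
    for gi, g in enumerate(graphs):
        seen: set[str] = set()
        for v in g.instances():
            key = normalize_label(v.label)
            if key and key not in seen:
                seen.add(key)
                cls = _portal_class_of(g, key)
                if cls is not None:
                    label_classes[key][gi] = cls

    for label in sorted(label_classes):
        per_source = label_classes[label]
        classes = sorted(set(per_source.values()))
        conflicting = any(
            schema.is_disjoint(c1, c2) for c1, c2 in combinations(classes, 2)
        )
        if not conflicting:
            continue

        winner: str | None = None
        method = "unresolved"
        score = 0.0
        if strategy in ("combined", "lookup-only"):
            if reference_lookup(label, codes) is not None:
                winner, method, score = "Disease", "lookup", 1.0
        if winner is None and strategy in ("combined", "vote-only"):
            vote = ClassVote(label, dict(Counter(per_source.values())))
            winner, score = vote_class(vote)
            best = max(vote.tally.values())
            n_tied = sum(1 for k in vote.tally.values() if k == best)
            method = "tie-break" if n_tied > 1 else "vote"

        report.resolutions.append(
            ConflictResolution(label, tuple(classes), winner, method, score)
        )
        if winner is None:
            logger.info("unresolved class conflict for %r: %s", label, classes)
            continue
        for g in graphs:
            for v in list(g.instances()):
                if normalize_label(v.label) == label:
                    g.edges = {
                        (s, p, o) for (s, p, o) in g.edges
                        if not (p == RDF_TYPE and s == v.id)
                    }
                    g.add_edge(v.id, RDF_TYPE, winner)

    return IntegratedDataGraph(graphs, list(integrated.mappings)), report


# ---------------------------------------------------------------------------
# instance matching


@dataclass
class MatchConfig:
    """Similarity aggregation parameters.

    Weighted mean of a syntactic score (best normalized string similarity
    over the label + alias sets) and a structural score (Jaccard overlap of
    normalized neighbor labels); candidates are blocked on (class, first
    character of a name) to stay sub-quadratic.
    """

    syntactic_weight: float = 0.6
    structural_weight: float = 0.4
    threshold: float = 0.85


@dataclass
class _Features:
    id: str
    classes: frozenset
    names: frozenset  # normalized label + aliases
    neighbors: frozenset  # normalized neighbor labels


def _instance_features(g: DataGraph) -> list[_Features]:
    types = g.type_map()
    out_edges: dict[str, set[tuple[str, str]]] = defaultdict(set)
    in_edges: dict[str, set[str]] = defaultdict(set)
    for s, p, o in g.edges:
        if p == RDF_TYPE:
            continue
        out_edges[s].add((p, o))
        in_edges[o].add(s)
    feats = []
    for v in sorted(g.instances(), key=lambda v: v.id):
        names = {normalize_label(v.label)}
        neighbors: set[str] = set()
        for p, o in out_edges.get(v.id, ()):
            target = g.vertices.get(o)
            if target is None:
                continue
            if p == "alias" and target.kind == "V":
                names.add(normalize_label(target.label))
            else:
                neighbors.add(normalize_label(target.label))
        for s in in_edges.get(v.id, ()):
            src = g.vertices.get(s)
            if src is not None and src.kind == "I":
                neighbors.add(normalize_label(src.label))
        feats.append(_Features(
            v.id,
            frozenset(types.get(v.id, ())),
            frozenset(n for n in names if n),
            frozenset(neighbors),
        ))
    return feats


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def match_instances(
    g1: DataGraph, g2: DataGraph, config: MatchConfig | None = None
) -> list[MappingAssertion]:
    """Derive one-to-one correspondences between two cleansed source graphs.

    Only instances sharing a class are candidates ("if two instances do not
    share a same class, they are unlikely to be aligned"); the aggregated
    score is kept when it reaches the threshold, and correspondences are
    made one-to-one greedily, best score first.
    """
    cfg = config or MatchConfig()
    f1 = _instance_features(g1)
    f2 = _instance_features(g2)

    def block_keys(f: _Features):
        return {(c, name[0]) for c in f.classes for name in f.names if name}

    index: dict[tuple, list[_Features]] = defaultdict(list)
    for f in f2:
        for key in block_keys(f):
            index[key].append(f)

    scored: list[tuple[float, str, str]] = []
    for a in f1:
        seen: set[str] = set()
        for key in block_keys(a):
            for b in index.get(key, ()):
                if b.id in seen or not (a.classes & b.classes):
                    continue
                seen.add(b.id)
                syntactic = max(
                    (string_similarity(x, y) for x in a.names for y in b.names),
                    default=0.0,
                )
                structural = _jaccard(a.neighbors, b.neighbors)
                score = (cfg.syntactic_weight * syntactic
                         + cfg.structural_weight * structural)
                if score >= cfg.threshold:
                    scored.append((score, a.id, b.id))

    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[str] = set()
    used2: set[str] = set()
    out = []
    for score, v1, v2 in scored:
        if v1 in used1 or v2 in used2:
            continue
        used1.add(v1)
        used2.add(v2)
        out.append(MappingAssertion(v1, v2, round(score, 6)))
    return out


# ---------------------------------------------------------------------------
# fusing matched clusters


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # canonical representative: lexicographically smallest URI
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def fuse(integrated: IntegratedDataGraph, schema: SchemaGraph | None = None) -> DataGraph:
    """Collapse matched instance clusters into one unified data graph.

    The transitive closure of the mapping assertions defines clusters; the
    canonical instance of a cluster is the member with the lexicographically
    smallest URI. All edges are re-pointed to canonical ids and (s, p, o)
    duplicates collapse. Source provenance is retained per vertex as a
    ``|``-joined tag. When ``schema`` is given, a cluster spanning two
    disjoint classes raises ``ValueError`` — the cleansing contract was
    breached upstream.
    """
    merged = merge_graphs(integrated.graphs)
    uf = _UnionFind()
    for m in integrated.mappings:
        uf.union(m.v1, m.v2)

    clusters: dict[str, list[str]] = defaultdict(list)
    for vid in merged.vertices:
        clusters[uf.find(vid)].append(vid)

    types = merged.type_map()
    if schema is not None:
        for root, members in clusters.items():
            cluster_types = set()
            for m in members:
                cluster_types |= types.get(m, set())
            for c1, c2 in combinations(sorted(cluster_types), 2):
                if schema.is_disjoint(c1, c2):
                    raise ValueError(
                        f"cluster {sorted(members)} spans disjoint classes "
                        f"{c1!r}/{c2!r}; cleanse before fusing"
                    )

    out = DataGraph()
    for root, members in clusters.items():
        canonical = merged.vertices[min(members)]
        sources = sorted({
            merged.vertices[m].source
            for m in members
            if merged.vertices[m].source is not None
        })
        if canonical.kind == "I":
            out.add_instance(root, canonical.label, "|".join(sources) or None)
        else:
            out.add_value(canonical.label)
    for s, p, o in merged.edges:
        out.add_edge(uf.find(s), p, o if p == RDF_TYPE else uf.find(o))
    return out


def label_identity_mappings(graphs: list[DataGraph]) -> list[MappingAssertion]:
    """Mapping assertions linking same-normalized-label instances across
    graphs (a trivial matcher used to audit cross-source class consistency)."""
    by_label: dict[str, list[str]] = defaultdict(list)
    for g in graphs:
        for v in g.instances():
            by_label[normalize_label(v.label)].append(v.id)
    out = []
    for label in sorted(by_label):
        ids = sorted(by_label[label])
        out.extend(MappingAssertion(ids[0], other, 1.0) for other in ids[1:])
    return out
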