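"""Distance-based EM extraction of a topic-centric subgraph.

The target knowledge base G_k (e.g. everything diabetes-related) is carved
out of the unified data graph G_d by alternating two steps from a handful of
seed instances:

* **E-step** — from the current central vertices, take all their relation
  neighbors and form the vertex-induced subgraph G_k^(t);
* **M-step** — score every vertex of G_k^(t) with eigenvector centrality and
  keep those above the threshold phi_c as the next central vertices.

Iteration stops when the center set reaches a fixed point (or after
``max_iterations``). The final membership cut keeps vertices whose
last-iteration centrality is at least phi_d; their attribute and type edges
are then re-attached. Both thresholds default to 0.01.

Centrality is computed over instances and relation edges only, treated as an
undirected unweighted graph, per connected component (components containing
no current center are dropped during the iteration, which keeps eigenvector
mass from drifting into off-topic islands).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
from scipy.sparse import identity

from .model import RDF_TYPE, DataGraph


@dataclass
class EMConfig:
    """EM thresholds and iteration limits.

    phi_c: centrality threshold for selecting the next centers (strict >).
    phi_d: membership threshold for the final subgraph (>=).
    Both default to 0.01 on L2-normalized centrality scores.
    """

    phi_c: float = 0.01
    phi_d: float = 0.01
    max_iterations: int = 10
    power_tol: float = 1e-8
    power_max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_c <= 1.0 and 0.0 < self.phi_d <= 1.0):
            raise ValueError("phi_c and phi_d must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class TraceRow(NamedTuple):
    iteration: int
    n_centers: int
    n_vertices: int
    n_edges: int


@dataclass
class EMState:
    """Snapshot of one EM iteration."""

    iteration: int
    centers: set[str]
    subgraph: DataGraph
    centrality: dict[str, float]

    def __post_init__(self) -> None:
        verts = self.subgraph.instance_ids()
        if not self.centers <= verts:
            raise ValueError("centers must be vertices of the induced subgraph")
        if set(self.centrality) != verts:
            raise ValueError("centrality must be defined exactly on the subgraph")
        if any(v < 0 for v in self.centrality.values()):
            raise ValueError("centrality scores must be non-negative")


def _relation_graph(g: DataGraph) -> nx.Graph:
    """Undirected simple graph over instance vertices and relation edges."""
    G = nx.Graph()
    G.add_nodes_from(g.instance_ids())
    for s, p, o in g.relation_edges():
        if s != o:
            G.add_edge(s, o)
    return G


def _component_scores(G: nx.Graph, nodes: list[str],
                      tol: float, max_iter: int) -> np.ndarray:
    """Power iteration on one connected component, L2-normalized.

    Iterates (A + I) x to guarantee convergence on bipartite components;
    A + I shares the Perron eigenvector of A on a connected component.
    """
    n = len(nodes)
    if n == 1:
        return np.ones(1)
    A = nx.to_scipy_sparse_array(G, nodelist=nodes, dtype=float)
    M = A + identity(n, format="csr")
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = M @ x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            return y
        x = y
    return x


def eigenvector_centrality(
    g: DataGraph, tol: float = 1e-8, max_iter: int = 1000
) -> dict[str, float]:
    """Dominant-eigenvector scores of the instance/relation graph.

    Computed independently per connected component with the component's
    score vector normalized to unit Euclidean norm (so a singleton component
    trivially scores 1.0). Raises ``ValueError`` on a graph without
    instances.
    """
    G = _relation_graph(g)
    if G.number_of_nodes() == 0:
        raise ValueError("cannot compute centrality of an empty graph")
    scores: dict[str, float] = {}
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        vec = _component_scores(G, nodes, tol, max_iter)
        scores.update(zip(nodes, np.abs(vec)))
    return scores


def expectation_step(g_d: DataGraph, centers: set[str]) -> DataGraph:
    """Induced subgraph of G_d on the centers and their relation neighbors.

    Neighbors are taken over relation edges in both directions; every
    relation edge of G_d between retained vertices is kept (the subgraph is
    induced, not a star), along with the retained instances' rdf:type edges.
    Attribute edges are excluded here and re-attached after the final cut.
    """
    instance_ids = g_d.instance_ids()
    missing = sorted(set(centers) - instance_ids)
    if missing:
        raise KeyError(f"unknown center vertices: {missing}")
    keep = set(centers)
    rel_edges = g_d.relation_edges()
    for s, _, o in rel_edges:
        if s in centers:
            keep.add(o)
        if o in centers:
            keep.add(s)
    sub = DataGraph()
    for vid in keep:
        v = g_d.vertices[vid]
        sub.add_instance(v.id, v.label, v.source)
    for s, p, o in rel_edges:
        if s in keep and o in keep:
            sub.add_edge(s, p, o)
    for s, p, o in g_d.edges:
        if p == RDF_TYPE and s in keep:
            sub.add_edge(s, p, o)
    return sub


def maximization_step(subgraph: DataGraph, phi_c: float) -> set[str]:
    """Vertices of the subgraph with centrality strictly above phi_c.

    May return the empty set (degenerate threshold; the caller stops).
    """
    scores = eigenvector_centrality(subgraph)
    return {v for v, c in scores.items() if c > phi_c}


def _drop_centerless_components(sub: DataGraph, centers: set[str]) -> DataGraph:
    G = _relation_graph(sub)
    keep: set[str] = set()
    for comp in nx.connected_components(G):
        if comp & centers:
            keep |= comp
    if keep == set(G.nodes):
        return sub
    out = DataGraph()
    for vid in keep:
        v = sub.vertices[vid]
        out.add_instance(v.id, v.label, v.source)
    for s, p, o in sub.edges:
        if (p == RDF_TYPE and s in keep) or (s in keep and o in keep):
            out.add_edge(s, p, o)
    return out


def _run(
    g_d: DataGraph, seeds: set[str], config: EMConfig
) -> tuple[DataGraph, list[TraceRow], EMState | None]:
    instance_ids = g_d.instance_ids()
    missing = sorted(set(seeds) - instance_ids)
    if missing:
        raise KeyError(f"seed vertices absent from the data graph: {missing}")
    if not seeds:
        raise ValueError("at least one seed vertex is required")

    centers = set(seeds)
    trace: list[TraceRow] = []
    state: EMState | None = None
    for t in range(1, config.max_iterations + 1):
        sub = expectation_step(g_d, centers)
        sub = _drop_centerless_components(sub, centers)
        scores = eigenvector_centrality(
            sub, tol=config.power_tol, max_iter=config.power_max_iter
        )
        new_centers = {v for v, c in scores.items() if c > config.phi_c}
        state = EMState(t, new_centers & sub.instance_ids(), sub, scores)
        trace.append(TraceRow(t, len(new_centers),
                              sub.n_instances, len(sub.relation_edges())))
        if new_centers == centers or not new_centers:
            centers = new_centers
            break
        centers = new_centers

    assert state is not None
    members = {v for v, c in state.centrality.items() if c >= config.phi_d}
    result = _induce_with_attributes(g_d, members)
    trace.append(TraceRow(state.iteration, len(centers),
                          result.n_instances, len(result.relation_edges())))
    return result, trace, state


def _induce_with_attributes(g_d: DataGraph, members: set[str]) -> DataGraph:
    """Induced subgraph on the member instances, with their attribute edges
    (and value vertices) and rdf:type edges re-attached."""
    out = DataGraph()
    for vid in members:
        v = g_d.vertices[vid]
        out.add_instance(v.id, v.label, v.source)
    for s, p, o in g_d.edges:
        if s not in members:
            continue
        if p == RDF_TYPE:
            out.add_edge(s, p, o)
            continue
        target = g_d.vertices.get(o)
        if target is None:
            continue
        if target.kind == "I":
            if o in members:
                out.add_edge(s, p, o)
        else:  # value vertex: re-attach
            out.add_value(target.label)
            out.add_edge(s, p, o)
    return out


def extract_topic_kb(
    g_d: DataGraph, seeds: Iterable[str], config: EMConfig | None = None
) -> DataGraph:
    """Extract the topic-centric subgraph G_k around the seed instances.

    Runs E/M iterations from the seeds until the center set is unchanged (or
    ``max_iterations``), then keeps vertices whose final centrality reaches
    phi_d, re-attaching their attribute and type edges. Deterministic for
    identical inputs (uniform power-iteration start vector).

    Raises ``KeyError`` listing seeds absent from the graph.
    """
    graph, _, _ = _run(g_d, set(seeds), config or EMConfig())
    return graph


def iteration_trace(
    g_d: DataGraph, seeds: Iterable[str], config: EMConfig | None = None
) -> list[TraceRow]:
    """Per-iteration (t, #centers, #vertices, #edges) diagnostics.

    Vertex/edge counts are over instances and relation edges. The final row
    reports the sizes of the extracted subgraph itself and matches
    :func:`extract_topic_kb` exactly.
    """
    _, trace, _ = _run(g_d, set(seeds), config or EMConfig())
    return trace
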