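"""Packaged evaluation experiments over synthetic corpora.

Reusable drivers for the three study-style evaluations:

* :func:`cleansing_experiment` — class-cleansing strategies (reference-list
  lookup, voting, combined) compared on restored-flip accuracy and conflict
  coverage, averaged over replicate corpora;
* :func:`matching_experiment` — instance-matching F1 with and without the
  cleansing pre-processing step;
* :func:`em_recovery_experiment` / :func:`seed_robustness_experiment` —
  planted-community recovery and seed-count stability of the EM extraction;
* :func:`zero_noise_experiment` — end-to-end identity on a noise-free corpus.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import combinations

import numpy as np

from .em import EMConfig, extract_topic_kb, iteration_trace
from .fusion import (
    IntegratedDataGraph,
    cleanse_classes,
    fuse,
    label_identity_mappings,
    match_instances,
)
from .model import default_diabetes_schema, validate
from .pipeline import portal_graphs_from_dumps
from .synthetic import (
    ALL7,
    CorpusConfig,
    class_assignments,
    cleansing_metrics,
    generate_code_list,
    generate_master,
    generate_portal_views,
    matching_metrics,
    planted_partition_config,
    topic_metrics,
)

SMALL_CLASSES = {
    "Disease": 60, "Symptom": 30, "WesternMedicine": 15, "TCM": 15,
    "Examination": 10, "Department": 8, "BodyStructure": 12,
}


def build_corpus(config: CorpusConfig, code_coverage: float = 0.6):
    """Materialize one corpus: master, truth, per-portal graphs, code list."""
    schema = default_diabetes_schema()
    master, truth = generate_master(config)
    dumps = generate_portal_views(master, truth, config)
    graphs = portal_graphs_from_dumps(dumps, schema)
    codes = generate_code_list(truth, code_coverage, seed=config.seed)
    return master, truth, graphs, codes


def _disjoint_count(graphs, schema) -> int:
    merged = fuse(IntegratedDataGraph(list(graphs),
                                      label_identity_mappings(list(graphs))))
    return sum(1 for v in validate(merged, schema) if v.rule == "disjoint")


def cleansing_experiment(seed: int, n_replicates: int = 3,
                         config: CorpusConfig | None = None) -> dict:
    """Compare cleansing strategies on replicate noisy corpora.

    Returns mean restored-flip accuracy and conflict coverage per strategy,
    plus the residual disjointness-violation count after combined cleansing
    (counted on the label-merged view of the sources).
    """
    schema = default_diabetes_schema()
    acc = {s: [] for s in ("combined", "vote-only", "lookup-only")}
    cov = {s: [] for s in acc}
    disjoint_before = []
    disjoint_after = []
    for r in range(n_replicates):
        cfg = replace(config or CorpusConfig(), seed=seed + r)
        _, truth, graphs, codes = build_corpus(cfg)
        integ = IntegratedDataGraph(list(graphs.values()))
        disjoint_before.append(_disjoint_count(integ.graphs, schema))
        for strategy in acc:
            cleansed, report = cleanse_classes(integ, codes, schema, strategy)
            m = cleansing_metrics(class_assignments(cleansed.graphs), truth)
            acc[strategy].append(m["flipped_accuracy"])
            cov[strategy].append(report.coverage)
            if strategy == "combined":
                disjoint_after.append(_disjoint_count(cleansed.graphs, schema))
    return {
        "restored_accuracy": {s: float(np.mean(v)) for s, v in acc.items()},
        "coverage": {s: float(np.mean(v)) for s, v in cov.items()},
        "disjoint_violations_before": int(sum(disjoint_before)),
        "disjoint_violations_after": int(sum(disjoint_after)),
        "n_replicates": n_replicates,
    }


def matching_experiment(seed: int, config: CorpusConfig | None = None) -> dict:
    """Instance-matching F1 with and without class cleansing."""
    schema = default_diabetes_schema()
    cfg = replace(config or CorpusConfig(), seed=seed)
    _, truth, graphs, codes = build_corpus(cfg)
    integ = IntegratedDataGraph(list(graphs.values()))
    cleansed, _ = cleanse_classes(integ, codes, schema)

    def run(gs):
        mappings = []
        for g1, g2 in combinations(gs, 2):
            mappings.extend(match_instances(g1, g2))
        return matching_metrics(mappings, truth)

    return {
        "with_cleansing": run(cleansed.graphs),
        "without_cleansing": run(integ.graphs),
    }


def plateau_iteration(trace, tolerance: float = 0.01) -> int:
    """First iteration whose vertex growth over the previous one is below
    ``tolerance`` (the trace's trailing summary row is ignored)."""
    rows = trace[:-1]
    for prev, cur in zip(rows, rows[1:]):
        if prev.n_vertices and \
                (cur.n_vertices - prev.n_vertices) / prev.n_vertices < tolerance:
            return cur.iteration
    return rows[-1].iteration


def em_recovery_experiment(seed: int, n_seeds: int = 6,
                           config: CorpusConfig | None = None,
                           em: EMConfig | None = None) -> dict:
    """Topic recovery on the 150/850 planted-partition graph."""
    cfg = config or planted_partition_config(seed=seed)
    master, truth = generate_master(cfg)
    rng = np.random.default_rng([seed, 4])
    seeds = rng.choice(sorted(truth.topic), size=n_seeds, replace=False).tolist()
    out = extract_topic_kb(master, seeds, em)
    trace = iteration_trace(master, seeds, em)
    metrics = topic_metrics(out, truth)
    return {
        "precision": metrics["precision"],
        "recall": metrics["recall"],
        "n_extracted": metrics["n_predicted"],
        "n_topic": metrics["n_actual"],
        "plateau_iteration": plateau_iteration(trace),
        "n_iterations": trace[-1].iteration,
        "trace": [tuple(r) for r in trace],
    }


def seed_robustness_experiment(seed: int, seed_counts=(2, 3, 6, 10),
                               config: CorpusConfig | None = None) -> dict:
    """Pairwise Jaccard similarity of extractions across seed-set sizes."""
    cfg = config or planted_partition_config(seed=seed)
    master, truth = generate_master(cfg)
    rng = np.random.default_rng([seed, 5])
    topic_sorted = sorted(truth.topic)
    extracted = {}
    for k in seed_counts:
        seeds = rng.choice(topic_sorted, size=k, replace=False).tolist()
        extracted[k] = extract_topic_kb(master, seeds).instance_ids()
    jaccards = {}
    for a, b in combinations(seed_counts, 2):
        inter = len(extracted[a] & extracted[b])
        union = len(extracted[a] | extracted[b])
        jaccards[f"{a}-{b}"] = inter / union if union else 1.0
    return {"jaccard": jaccards, "min_jaccard": min(jaccards.values())}


def zero_noise_experiment(seed: int) -> dict:
    """Full pipeline on a noise-free, fully-covered corpus.

    With every noise rate at zero, duplication 1.0 and no background edges,
    the extracted topic KB must coincide exactly with the planted topic
    community's closed neighborhood.
    """
    schema = default_diabetes_schema()
    cfg = CorpusConfig(
        seed=seed,
        instances_per_class=dict(SMALL_CLASSES),
        topic_size=40,
        p_out=0.0,
        coverage={p: ALL7 for p in CorpusConfig().portals},
        duplication_rate=1.0,
        alias_rate=0.0,
        class_flip_rate=0.0,
        distractor_rate=0.0,
    )
    master, truth, graphs, codes = build_corpus(cfg, code_coverage=1.0)
    integ = IntegratedDataGraph(list(graphs.values()))
    cleansed, _ = cleanse_classes(integ, codes, schema)
    mappings = []
    for g1, g2 in combinations(cleansed.graphs, 2):
        mappings.extend(match_instances(g1, g2))
    cleansed.mappings = mappings
    fused = fuse(cleansed, schema)

    rng = np.random.default_rng([seed, 6])
    seed_ids = rng.choice(sorted(truth.topic), size=6, replace=False).tolist()
    seed_uris = [sorted(truth.duplicates[mid].values())[0] for mid in seed_ids]
    dkb = extract_topic_kb(fused, seed_uris)

    reverse = truth.portal_to_master()
    extracted_master = {reverse[i] for i in dkb.instance_ids()}
    closed = truth.closed_topic()
    metrics = topic_metrics(dkb, truth, closed=True)
    return {
        "exact": extracted_master == closed,
        "precision": metrics["precision"],
        "recall": metrics["recall"],
        "f1": metrics["f1"],
        "n_extracted": len(extracted_master),
        "n_closed_topic": len(closed),
    }
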