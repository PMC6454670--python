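"""Class cleansing, voting, instance matching and cluster fusion."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dkb.fusion import (
    ClassVote,
    CodeEntry,
    IntegratedDataGraph,
    MappingAssertion,
    MatchConfig,
    ReferenceCodeList,
    cleanse_classes,
    fuse,
    label_identity_mappings,
    match_instances,
    reference_lookup,
    string_similarity,
    vote_class,
)
from dkb.model import RDF_TYPE, DataGraph, validate
from dkb.synthetic import class_assignments, cleansing_metrics, matching_metrics


# ---------------------------------------------------------------------------
# reference lookup


class TestReferenceLookup:
    def test_verbatim_hit_is_disease(self):
        codes = ReferenceCodeList([CodeEntry("E11", "type 2 diabetes", ("t2dm",))])
        assert reference_lookup("Type 2 Diabetes", codes) == "Disease"
        assert reference_lookup("t2dm", codes) == "Disease"

    def test_miss_is_none(self):
        codes = ReferenceCodeList([CodeEntry("E11", "diabetes")])
        assert reference_lookup("polydipsia", codes) is None

    def test_empty_label_rejected(self):
        codes = ReferenceCodeList([])
        with pytest.raises(ValueError):
            reference_lookup("  ", codes)

    def test_planted_membership(self):
        rng = np.random.default_rng(7)
        labels = [f"term{k:04d}" for k in range(1000)]
        planted = set(rng.choice(labels, 100, replace=False).tolist())
        codes = ReferenceCodeList(
            [CodeEntry(f"C{i}", lab) for i, lab in enumerate(sorted(planted))])
        hits = {lab for lab in labels if reference_lookup(lab, codes) == "Disease"}
        assert hits == planted

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError):
            ReferenceCodeList([CodeEntry("C1", "a"), CodeEntry("C1", "b")])


# ---------------------------------------------------------------------------
# voting


class TestVoteClass:
    def test_majority(self):
        assert vote_class(ClassVote("x", {"Disease": 3, "Symptom": 2})) == ("Disease", 0.6)

    def test_unanimous_single_source(self):
        assert vote_class(ClassVote("x", {"Disease": 1})) == ("Disease", 1.0)

    def test_empty_tally_raises(self):
        with pytest.raises(ValueError):
            vote_class(ClassVote("x", {}))

    def test_tie_prefers_disease_then_lexicographic(self):
        assert vote_class(ClassVote("x", {"Symptom": 2, "Disease": 2}))[0] == "Disease"
        assert vote_class(ClassVote("x", {"Symptom": 1, "Examination": 1}))[0] == "Examination"

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.dictionaries(
        st.sampled_from(["Disease", "Symptom", "TCM", "Examination", "BodyStructure"]),
        st.integers(1, 9), min_size=1, max_size=5))
    def test_matches_brute_force_argmax(self, tally):
        winner, score = vote_class(ClassVote("x", tally))
        n = sum(tally.values())
        best = max(tally.values())
        argmax = sorted(c for c, k in tally.items() if k == best)
        assert score == best / n
        assert winner == ("Disease" if "Disease" in argmax else argmax[0])


# ---------------------------------------------------------------------------
# cleansing


def _portal(ns: str, label: str, cls: str, source: str | None = None) -> DataGraph:
    g = DataGraph()
    g.add_instance(f"kb://{ns}/x", label, source or ns)
    g.add_edge(f"kb://{ns}/x", RDF_TYPE, cls)
    return g


class TestCleanseClasses:
    def test_majority_vote_resolves_conflict(self, schema):
        graphs = [_portal(f"p{k}", "hydronephrosis", "Disease") for k in range(3)]
        graphs += [_portal(f"q{k}", "hydronephrosis", "Symptom") for k in range(2)]
        codes = ReferenceCodeList([])
        cleansed, report = cleanse_classes(
            IntegratedDataGraph(graphs), codes, schema)
        assert report.n_conflicts == 1
        assert report.resolutions[0].winner == "Disease"
        assert report.resolutions[0].method == "vote"
        for g in cleansed.graphs:
            for v in g.instances():
                assert g.types_of(v.id) == {"Disease"}

    def test_lookup_has_absolute_precedence(self, schema):
        # every portal votes Symptom, but the label is in the code list
        graphs = [_portal(f"p{k}", "ketoacidosis", "Symptom") for k in range(4)]
        graphs.append(_portal("q0", "ketoacidosis", "Disease"))
        codes = ReferenceCodeList([CodeEntry("E10", "ketoacidosis")])
        cleansed, report = cleanse_classes(
            IntegratedDataGraph(graphs), codes, schema)
        assert report.resolutions[0].method == "lookup"
        assert all(g.types_of(next(g.instances()).id) == {"Disease"}
                   for g in cleansed.graphs)

    def test_non_conflicting_labels_untouched(self, schema):
        graphs = [_portal("p0", "insulin", "WesternMedicine"),
                  _portal("p1", "insulin", "WesternMedicine")]
        cleansed, report = cleanse_classes(
            IntegratedDataGraph(graphs), ReferenceCodeList([]), schema)
        assert report.n_conflicts == 0
        assert [g.edges for g in cleansed.graphs] == [g.edges for g in graphs]

    def test_idempotent(self, small_corpus, schema):
        _, _, _, _, graphs, codes = small_corpus
        integ = IntegratedDataGraph(list(graphs.values()))
        once, report1 = cleanse_classes(integ, codes, schema)
        twice, report2 = cleanse_classes(once, codes, schema)
        assert report2.n_conflicts == 0
        assert [g.edges for g in twice.graphs] == [g.edges for g in once.graphs]

    def test_resolved_labels_have_no_disjoint_violations(self, small_corpus, schema):
        """After cleansing, merging same-label instances breaches no
        disjointness axiom (before cleansing it does)."""
        _, _, truth, _, graphs, codes = small_corpus
        integ = IntegratedDataGraph(list(graphs.values()))

        def disjoint_count(gs):
            merged = fuse(IntegratedDataGraph(list(gs), label_identity_mappings(list(gs))))
            return sum(1 for v in validate(merged, schema) if v.rule == "disjoint")

        assert disjoint_count(integ.graphs) > 0  # planted flips conflict
        cleansed, report = cleanse_classes(integ, codes, schema)
        assert report.coverage == 1.0
        assert disjoint_count(cleansed.graphs) == 0

    def test_strategy_ordering_on_planted_flips(self, small_corpus, schema):
        """Combined beats voting-only on restored flips; voting-only beats
        lookup-only on coverage."""
        _, _, truth, _, graphs, codes = small_corpus
        integ = IntegratedDataGraph(list(graphs.values()))
        acc, cov = {}, {}
        for strategy in ("combined", "vote-only", "lookup-only"):
            cleansed, report = cleanse_classes(integ, codes, schema, strategy)
            m = cleansing_metrics(class_assignments(cleansed.graphs), truth)
            acc[strategy] = m["flipped_accuracy"]
            cov[strategy] = report.coverage
        assert acc["combined"] >= acc["vote-only"]
        assert cov["vote-only"] > cov["lookup-only"]


# ---------------------------------------------------------------------------
# matching


def _twin(ns: str, label: str, cls: str, neighbors: tuple[str, ...] = ()) -> DataGraph:
    g = DataGraph()
    uri = f"kb://{ns}/a"
    g.add_instance(uri, label, ns)
    g.add_edge(uri, RDF_TYPE, cls)
    for k, nb in enumerate(neighbors):
        nb_uri = f"kb://{ns}/n{k}"
        g.add_instance(nb_uri, nb, ns)
        g.add_edge(nb_uri, RDF_TYPE, "Symptom")
        g.add_edge(uri, "sign", nb_uri)
    return g


class TestMatchInstances:
    def test_identical_twins_score_one(self):
        g1 = _twin("p", "diabetes", "Disease", ("thirst", "fatigue"))
        g2 = _twin("q", "diabetes", "Disease", ("thirst", "fatigue"))
        matches = match_instances(g1, g2)
        by_pair = {m.pair(): m.score for m in matches}
        assert by_pair[frozenset({"kb://p/a", "kb://q/a"})] == 1.0

    def test_disjoint_classes_never_candidates(self):
        g1 = _twin("p", "hydronephrosis", "Disease")
        g2 = _twin("q", "hydronephrosis", "Symptom")
        assert match_instances(g1, g2) == []

    def test_one_to_one(self):
        g1 = DataGraph()
        for k in range(2):
            g1.add_instance(f"kb://p/a{k}", "metformin", "p")
            g1.add_edge(f"kb://p/a{k}", RDF_TYPE, "WesternMedicine")
        g2 = _twin("q", "metformin", "WesternMedicine")
        matches = match_instances(g1, g2)
        assert len(matches) == 1  # greedy best-first, one per target

    def test_against_all_pairs_oracle(self, small_corpus):
        """Blocked matcher equals exhaustive all-pairs scoring on a small
        two-portal slice (<= 200 instances per side)."""
        _, _, _, _, graphs, _ = small_corpus
        names = sorted(graphs)
        g1, g2 = graphs[names[0]], graphs[names[1]]
        cfg = MatchConfig()
        got = {(m.v1, m.v2, m.score) for m in match_instances(g1, g2, cfg)}

        from dkb.fusion import _instance_features, _jaccard

        scored = []
        for a in _instance_features(g1):  # exhaustive: no blocking at all
            for b in _instance_features(g2):
                if not (a.classes & b.classes):
                    continue
                syn = max((string_similarity(x, y)
                           for x in a.names for y in b.names), default=0.0)
                score = cfg.syntactic_weight * syn + \
                    cfg.structural_weight * _jaccard(a.neighbors, b.neighbors)
                if score >= cfg.threshold:
                    scored.append((score, a.id, b.id))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        used1, used2, expected = set(), set(), set()
        for score, v1, v2 in scored:
            if v1 in used1 or v2 in used2:
                continue
            used1.add(v1)
            used2.add(v2)
            expected.add((v1, v2, round(score, 6)))
        assert got == expected

    def test_alias_substitution_recovered(self, small_corpus):
        """With 20% alias noise the matcher still finds most planted pairs."""
        _, _, truth, _, graphs, _ = small_corpus
        mappings = []
        for a, b in combinations(sorted(graphs), 2):
            mappings.extend(match_instances(graphs[a], graphs[b]))
        m = matching_metrics(mappings, truth)
        assert m["precision"] > 0.95
        assert m["recall"] > 0.5

    def test_cleansing_improves_f1(self, small_corpus, schema):
        _, _, truth, _, graphs, codes = small_corpus
        integ = IntegratedDataGraph(list(graphs.values()))
        cleansed, _ = cleanse_classes(integ, codes, schema)

        def f1(gs):
            mappings = []
            for g1, g2 in combinations(gs, 2):
                mappings.extend(match_instances(g1, g2))
            return matching_metrics(mappings, truth)["f1"]

        assert f1(cleansed.graphs) > f1(integ.graphs)


# ---------------------------------------------------------------------------
# fusing


class TestFuse:
    def test_edge_union_of_matched_pair(self, schema):
        g1, g2 = DataGraph(), DataGraph()
        g1.add_instance("kb://p/a", "diabetes", "p")
        g2.add_instance("kb://q/a", "diabetes", "q")
        for k in range(3):
            g1.add_value(f"s{k}")
            g1.add_edge("kb://p/a", "alias", f"value:s{k}")
        for k in range(2, 6):  # one shared: s2
            g2.add_value(f"s{k}")
            g2.add_edge("kb://q/a", "alias", f"value:s{k}")
        integ = IntegratedDataGraph(
            [g1, g2], [MappingAssertion("kb://p/a", "kb://q/a", 1.0)])
        fused = fuse(integ)
        assert fused.n_instances == 1
        assert len(fused.edges) == 6  # 3 + 4 - 1 shared
        assert fused.vertices["kb://p/a"].source == "p|q"

    def test_transitive_closure_cluster(self):
        gs = []
        for ns in ("p", "q", "r"):
            g = DataGraph()
            g.add_instance(f"kb://{ns}/x", "metformin", ns)
            gs.append(g)
        integ = IntegratedDataGraph(gs, [
            MappingAssertion("kb://p/x", "kb://q/x", 1.0),
            MappingAssertion("kb://q/x", "kb://r/x", 1.0),
        ])
        fused = fuse(integ)
        assert fused.instance_ids() == {"kb://p/x"}

    def test_disjoint_cluster_raises_with_schema(self, schema):
        g1 = _portal("p", "hydronephrosis", "Disease")
        g2 = _portal("q", "hydronephrosis", "Symptom")
        integ = IntegratedDataGraph(
            [g1, g2], [MappingAssertion("kb://p/x", "kb://q/x", 1.0)])
        with pytest.raises(ValueError, match="disjoint"):
            fuse(integ, schema)

    def test_never_increases_triples(self, small_corpus, schema):
        _, _, _, _, graphs, codes = small_corpus
        integ = IntegratedDataGraph(list(graphs.values()))
        cleansed, _ = cleanse_classes(integ, codes, schema)
        mappings = []
        for g1, g2 in combinations(cleansed.graphs, 2):
            mappings.extend(match_instances(g1, g2))
        cleansed.mappings = mappings
        fused = fuse(cleansed, schema)
        total_distinct = len(set().union(*(g.edges for g in cleansed.graphs)))
        assert len(fused.edges) <= total_distinct

    def test_cluster_count_matches_union_find_oracle(self, clean_corpus, schema):
        """On the noise-free corpus the fused instance count equals the
        union-find closure over the planted duplicate clusters."""
        _, _, truth, _, graphs, codes = clean_corpus
        integ = IntegratedDataGraph(list(graphs.values()))
        mappings = []
        for g1, g2 in combinations(integ.graphs, 2):
            mappings.extend(match_instances(g1, g2))
        integ.mappings = mappings
        fused = fuse(integ, schema)
        # oracle: planted clusters = one per master instance with >= 1 placement
        expected = sum(1 for p in truth.duplicates.values() if p)
        assert fused.n_instances == expected
        total = sum(g.n_instances for g in integ.graphs)
        assert fused.n_instances < total
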