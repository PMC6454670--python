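"""Entry-to-property mapping, vertical partitioning, D2R materialization."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dkb.extraction import (
    Entry,
    HeuristicLexicon,
    NavRow,
    PortalDump,
    PropertyTable,
    d2r_materialize,
    extract_tables,
    map_entry_to_property,
    repartition,
)
from dkb.model import RDF_TYPE, normalize_label


# ---------------------------------------------------------------------------
# heuristic word mapping


@pytest.mark.parametrize("sentence,expected", [
    ("Common Complications", "complication"),
    ("  common   COMPLICATION list ", "complication"),
    ("", None),
    ("popular articles", None),
    ("clinical manifestations of this disease", "sign"),
    ("Alias", "alias"),
])
def test_topic_sentence_mapping_examples(lexicon, sentence, expected):
    assert map_entry_to_property(sentence, lexicon) == expected


@st.composite
def lexicons_and_sentences(draw):
    words = st.text(alphabet="abcdef ", min_size=1, max_size=6).map(str.strip).filter(bool)
    n_props = draw(st.integers(1, 5))
    table = {
        f"p{k}": set(draw(st.lists(words, min_size=1, max_size=3, unique=True)))
        for k in range(n_props)
    }
    priority = draw(st.permutations(sorted(table)))
    sentence = draw(st.text(alphabet="abcdef ", max_size=25))
    return HeuristicLexicon(table, list(priority)), sentence


@settings(max_examples=200, derandomize=True, deadline=None)
@given(lexicons_and_sentences())
def test_mapping_matches_exhaustive_scan(case):
    """Same answer as scanning every (property, word) pair in priority order."""
    lexicon, sentence = case
    expected = None
    norm = normalize_label(sentence)
    for prop in lexicon.priority:
        if norm and any(normalize_label(w) in norm for w in lexicon.words[prop]):
            expected = prop
            break
    assert map_entry_to_property(sentence, lexicon) == expected


def test_lexicon_rejects_empty_word_sets():
    with pytest.raises(ValueError):
        HeuristicLexicon({"p": set()})
    with pytest.raises(ValueError):
        HeuristicLexicon({"p": {"w"}}, priority=["p", "ghost"])


# ---------------------------------------------------------------------------
# extract_tables


def _toy_dump() -> PortalDump:
    return PortalDump(
        source="39health",
        navigation=[
            NavRow("iixtnb", "type 2 diabetes", "Disease"),
            NavRow("gxy", "hypertension", "Disease"),
        ],
        details={
            "iixtnb": [
                Entry("list", "Common Complications", ("hypertension",)),
                Entry("infobox", "alias", ("t2dm", "")),
                Entry("list", "patient stories", ("noise",)),
            ],
        },
    )


class TestExtractTables:
    def test_complication_list_becomes_table_row(self, lexicon):
        result = extract_tables(_toy_dump(), lexicon)
        comp = {t.name: t for t in result.property_tables}["complication"]
        assert comp.rows == [("iixtnb", "hypertension")]

    def test_class_table_covers_navigation(self, lexicon):
        result = extract_tables(_toy_dump(), lexicon)
        assert result.class_table.rows == [
            ("iixtnb", "Disease"), ("gxy", "Disease")]
        assert result.label_table.rows == [
            ("iixtnb", "type 2 diabetes"), ("gxy", "hypertension")]

    def test_skip_counters(self, lexicon):
        result = extract_tables(_toy_dump(), lexicon)
        assert result.unmapped_entries == 1  # "patient stories"
        assert result.empty_values == 1  # empty alias payload element

    def test_no_detail_records_yields_only_class_rows(self, lexicon):
        dump = PortalDump("x", [NavRow("a", "a lbl", "Symptom")])
        result = extract_tables(dump, lexicon)
        assert len(result.class_table) == 1
        assert result.property_tables == []

    def test_invariant_breach_raises(self, lexicon):
        dump = PortalDump("x", [NavRow("a", "l", "Disease")],
                          {"ghost": [Entry("list", "alias", ("v",))]})
        with pytest.raises(ValueError, match="detail records"):
            extract_tables(dump, lexicon)

    def test_row_count_matches_enumeration(self, small_corpus, lexicon):
        """Total table rows equal a brute-force count of mapped payloads."""
        _, _, _, dumps, _, _ = small_corpus
        for dump in dumps[:3]:
            result = extract_tables(dump, lexicon)
            expected = set()
            for ident, entries in dump.details.items():
                for e in entries:
                    prop = map_entry_to_property(e.topic, lexicon)
                    if prop is None:
                        continue
                    for value in e.payload:
                        if value.strip():
                            expected.add((prop, ident, value))
            got = sum(len(t) for t in result.property_tables)
            assert got == len(expected)

    def test_tables_are_two_column_single_property(self, small_corpus, lexicon):
        _, _, _, dumps, _, _ = small_corpus
        result = extract_tables(dumps[0], lexicon)
        names = [t.name for t in result.property_tables]
        assert len(names) == len(set(names))
        for t in result.property_tables:
            assert all(len(row) == 2 for row in t.rows)
            assert len(set(t.rows)) == len(t.rows)  # no duplicated rows


# ---------------------------------------------------------------------------
# D2R materialization


class TestD2R:
    def test_single_row_class_table(self, schema):
        ct = PropertyTable(RDF_TYPE, [("d1", "Disease")])
        result = d2r_materialize(ct, [], schema, "kb://x/")
        g = result.graph
        assert g.types_of("kb://x/d1") == {"Disease"}
        assert result.rejects == []

    def test_object_resolving_to_instance_becomes_relation_edge(self, schema):
        ct = PropertyTable(RDF_TYPE, [("tnb", "Disease"), ("dy", "Symptom")])
        lt = PropertyTable("label", [("tnb", "diabetes"), ("dy", "polydipsia")])
        st_ = PropertyTable("sign", [("tnb", "polydipsia")])
        g = d2r_materialize(ct, [st_], schema, "kb://x/", lt).graph
        assert ("kb://x/tnb", "sign", "kb://x/dy") in g.edges

    def test_unresolved_object_becomes_value_vertex(self, schema):
        ct = PropertyTable(RDF_TYPE, [("tnb", "Disease")])
        st_ = PropertyTable("sign", [("tnb", "polyuria")])
        g = d2r_materialize(ct, [st_], schema, "kb://x/").graph
        assert ("kb://x/tnb", "sign", "value:polyuria") in g.edges
        assert g.vertices["value:polyuria"].kind == "V"

    def test_unknown_class_label_quarantined(self, schema):
        ct = PropertyTable(RDF_TYPE, [("a", "Disease"), ("b", "Wizardry")])
        result = d2r_materialize(ct, [], schema, "kb://x/")
        assert result.rejects == [(RDF_TYPE, "b", "Wizardry", "unknown class label")]
        assert "kb://x/b" in result.graph.vertices  # graph still produced
        assert result.graph.types_of("kb://x/b") == set()

    def test_edges_match_row_by_row_translation(self, small_corpus, lexicon, schema):
        """Resulting edge set equals independent row-by-row translation."""
        _, _, _, dumps, _, _ = small_corpus
        dump = dumps[0]
        t = extract_tables(dump, lexicon)
        ns = "kb://check/"
        g = d2r_materialize(t.class_table, t.property_tables, schema, ns,
                            t.label_table).graph

        labels = dict(t.label_table.rows)
        by_label = {}
        for ident in labels:
            by_label.setdefault(normalize_label(labels[ident]), ns + ident)
        expected = set()
        for ident, cls_label in t.class_table.rows:
            cls = schema.class_by_label(cls_label)
            if cls:
                expected.add((ns + ident, RDF_TYPE, cls))
        for table in t.property_tables:
            for subj, obj in table.rows:
                if table.name in schema.relations() and normalize_label(obj) in by_label:
                    expected.add((ns + subj, table.name, by_label[normalize_label(obj)]))
                else:
                    expected.add((ns + subj, table.name, "value:" + obj))
        assert g.edges == expected

    def test_every_instance_carries_source_tag(self, small_corpus):
        _, _, _, _, graphs, _ = small_corpus
        for name, g in graphs.items():
            assert all(v.source == name for v in g.instances())

    def test_vertical_partitioning_round_trip(self, small_corpus, lexicon, schema):
        """materialize then re-partition reproduces the tables (row order aside)."""
        _, _, _, dumps, _, _ = small_corpus
        for dump in dumps[:3]:
            t = extract_tables(dump, lexicon)
            ns = f"kb://{dump.source}/"
            g = d2r_materialize(t.class_table, t.property_tables, schema, ns,
                                t.label_table, dump.source).graph
            ct, lt, tables = repartition(g, ns, schema)
            assert ct == t.class_table
            assert lt == t.label_table
            assert {x.name: x for x in tables} == {x.name: x for x in t.property_tables}
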