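"""Shared fixtures: the default schema and small synthetic corpora.

Corpus fixtures are session-scoped; tests must not mutate them (copy first).
"""

from __future__ import annotations

import pytest

from dkb.extraction import default_lexicon
from dkb.model import default_diabetes_schema
from dkb.pipeline import portal_graphs_from_dumps
from dkb.synthetic import (
    ALL7,
    CorpusConfig,
    generate_code_list,
    generate_master,
    generate_portal_views,
)

SMALL_CLASSES = {
    "Disease": 60,
    "Symptom": 30,
    "WesternMedicine": 15,
    "TCM": 15,
    "Examination": 10,
    "Department": 8,
    "BodyStructure": 12,
}


@pytest.fixture(scope="session")
def schema():
    return default_diabetes_schema()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def build_corpus(config: CorpusConfig, code_coverage: float = 0.6):
    """Generate master, truth, dumps, per-portal graphs and a code list."""
    schema = default_diabetes_schema()
    master, truth = generate_master(config)
    dumps = generate_portal_views(master, truth, config)
    graphs = portal_graphs_from_dumps(dumps, schema)
    codes = generate_code_list(truth, code_coverage, seed=config.seed)
    return master, truth, dumps, graphs, codes


@pytest.fixture(scope="session")
def small_corpus():
    """A small noisy 8-portal corpus with planted flips and aliases."""
    config = CorpusConfig(
        seed=1,
        instances_per_class=dict(SMALL_CLASSES),
        topic_size=40,
        duplication_rate=0.5,
    )
    return config, *build_corpus(config)


@pytest.fixture(scope="session")
def clean_corpus():
    """Noise-free corpus: full coverage, every instance in every portal."""
    config = CorpusConfig(
        seed=5,
        instances_per_class=dict(SMALL_CLASSES),
        topic_size=40,
        p_out=0.0,
        coverage={p: ALL7 for p in CorpusConfig().portals},
        duplication_rate=1.0,
        alias_rate=0.0,
        class_flip_rate=0.0,
        distractor_rate=0.0,
    )
    return config, *build_corpus(config, code_coverage=1.0)
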