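import pytest

from agemap import mining, store, synthetic
from agemap.lexicon import build_lexicon

TOY_OBO = """format-version: 1.2

[Term]
id: DOID:9351
name: diabetes mellitus
synonym: "DM" EXACT []

[Term]
id: DOID:1240
name: leukemia
synonym: "leukaemia" EXACT []

[Term]
id: DOID:2355
name: anemia

[Term]
id: DOID:0001
name: old disease
is_obsolete: true
"""


@pytest.fixture(scope="session")
def toy_lexicon():
    return build_lexicon(TOY_OBO)


@pytest.fixture(scope="session")
def specs():
    return synthetic.example_specs()


@pytest.fixture(scope="session")
def clean_corpus(specs, tmp_path_factory):
    """Distractor-free template corpus with gold annotations."""
    text, gold = synthetic.generate_corpus(specs, n_distractors=0, seed=11)
    path = tmp_path_factory.mktemp("corpus") / "clean.medline"
    path.write_text(text)
    return mining.read_medline(path), gold


@pytest.fixture(scope="session")
def mixed_corpus(specs, tmp_path_factory):
    """Corpus with age-only / disease-only / empty distractors and rat abstracts."""
    text, gold = synthetic.generate_corpus(specs, n_distractors=30, seed=7, n_blocked=6)
    path = tmp_path_factory.mktemp("corpus") / "mixed.medline"
    path.write_text(text)
    return mining.read_medline(path), gold


@pytest.fixture(scope="session")
def synthetic_lexicon(specs):
    return build_lexicon(synthetic.generate_ontology(specs))


@pytest.fixture(scope="session")
def mined_store(clean_corpus, synthetic_lexicon, tmp_path_factory):
    corpus, _ = clean_corpus
    instances = mining.mine_corpus(corpus, synthetic_lexicon, synthetic.DEFAULT_STRAINS)
    path = tmp_path_factory.mktemp("store") / "evidence"
    store.write_store(instances, path)
    return store.read_store(path)
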