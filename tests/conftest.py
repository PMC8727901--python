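import pytest

from chemrext import synthetic
from chemrext.pipeline import PipelineConfig, train_pipeline
from chemrext.standoff import (
    Document,
    EntityLabel,
    EntityMention,
    RelationLabel,
    RelationMention,
)
from chemrext.preprocess import tokenize_document


@pytest.fixture(scope="session")
def small_corpus():
    """60 deterministic synthetic documents shared across read-only tests."""
    return synthetic.generate_corpus(
        synthetic.GeneratorConfig(n_documents=60, seed=7)
    )


@pytest.fixture(scope="session")
def trained_small_pipeline(small_corpus):
    """A pipeline trained on 45 docs; the remaining 15 serve as held-out."""
    train, test = small_corpus[:45], small_corpus[45:]
    pipe = train_pipeline(train, PipelineConfig(tagger_epochs=6))
    return pipe, train, test


def make_doc(text, entity_specs, relation_specs=(), doc_id="doc"):
    """Build a tokenized Document from (surface, label) or explicit specs.

    entity_specs: list of (surface, label) — located by first occurrence —
    or (start, end, label).  relation_specs: (trigger_idx, argument_idx,
    relation_label) indices into the entity list.
    """
    entities = []
    cursor = 0
    for i, spec in enumerate(entity_specs):
        if isinstance(spec[0], int):
            start, end, label = spec
        else:
            surface, label = spec
            start = text.index(surface, cursor)
            end = start + len(surface)
            cursor = start + 1
        entities.append(
            EntityMention(f"T{i + 1}", label, start, end, text[start:end])
        )
    relations = [
        RelationMention(f"R{i + 1}", rel_label, entities[t], entities[a])
        for i, (t, a, rel_label) in enumerate(relation_specs)
    ]
    doc = Document(doc_id=doc_id, text=text, entities=entities,
                   relations=relations)
    tokenize_document(doc)
    return doc


@pytest.fixture
def doc_factory():
    return make_doc


E = EntityLabel
R = RelationLabel
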