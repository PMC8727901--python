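import copy

import pytest

from chemrext.rules import (
    RuleConfig,
    apply_all_rules,
    apply_relation_rules,
    link_yield_sentence,
    merge_satag_and_link,
    relabel_heading_compounds,
    replay_traces,
    trim_compound_prefix,
    trim_example_label,
)
from chemrext.standoff import EntityLabel, RelationLabel
from chemrext.pipeline import predict_corpus

E = EntityLabel


def _single(doc):
    return doc.entities[0]


@pytest.mark.parametrize(
    "surface, trimmed",
    [
        ("Example 95", "95"),
        ("(Step 2)", "2"),
        ("[Intermediate 7]", "7"),
        ("reference example 3", "3"),
        ("95", "95"),
    ],
)
def test_trim_example_label_strips_lead_words_and_brackets(
    doc_factory, surface, trimmed
):
    doc = doc_factory(f"{surface} was prepared.", [(surface, E.EXAMPLE_LABEL)])
    out = trim_example_label(_single(doc), doc.text)
    assert out.surface == trimmed
    assert doc.text[out.start : out.end] == trimmed
    # shrink only: the trimmed span sits inside the original span
    assert out.start >= _single(doc).start and out.end <= _single(doc).end


def test_trim_example_label_never_empties_a_span(doc_factory):
    doc = doc_factory("Example was prepared.", [("Example", E.EXAMPLE_LABEL)])
    out = trim_example_label(_single(doc), doc.text)
    assert out.surface == "Example"  # unchanged rather than emptied


@pytest.mark.parametrize(
    "surface, label, trimmed",
    [
        ("compound 1-0003", E.OTHER_COMPOUND, "1-0003"),
        ("Example 56A", E.REACTION_PRODUCT, "56A"),
        ("compound sodium chloride", E.OTHER_COMPOUND,
         "compound sodium chloride"),
        ("sodium chloride", E.OTHER_COMPOUND, "sodium chloride"),
    ],
)
def test_trim_compound_prefix_requires_numeric_pattern(
    doc_factory, surface, label, trimmed
):
    doc = doc_factory(f"Add {surface} now.", [(surface, label)])
    out = trim_compound_prefix(_single(doc), doc.text)
    assert out.surface == trimmed


def test_relabel_compounds_by_heading_structure(doc_factory):
    text = (
        "EXAMPLE 48\n"
        "Synthesis of 2-bromoaniline and 4-chlorophenol\n"
        "48.1 7-fluoroquinoline\n"
        "A solution was stirred."
    )
    doc = doc_factory(
        text,
        [
            ("48", E.EXAMPLE_LABEL),
            ("2-bromoaniline", E.REACTION_PRODUCT),   # mislabeled by the tagger
            ("4-chlorophenol", E.REACTION_PRODUCT),   # mislabeled by the tagger
            ("7-fluoroquinoline", E.OTHER_COMPOUND),  # mislabeled by the tagger
        ],
    )
    traces = []
    relabel_heading_compounds(doc, traces)
    labels = [m.label for m in doc.entities[1:]]
    assert labels == [E.OTHER_COMPOUND, E.OTHER_COMPOUND, E.REACTION_PRODUCT]
    assert len(traces) == 3


def test_relabel_without_substep_heading_is_noop(doc_factory):
    doc = doc_factory(
        "EXAMPLE 9\nA solution of 2-bromoaniline was stirred.",
        [("2-bromoaniline", E.REACTION_PRODUCT)],
    )
    relabel_heading_compounds(doc)
    assert doc.entities[0].label is E.REACTION_PRODUCT


def test_merge_satag_repairs_split_and_links_chemical(doc_factory):
    text = ("the residue was dissolved in EtOAc and washed with sat. aq. "
            "NH4Cl")
    doc = doc_factory(
        text,
        [
            ("dissolved", E.WORKUP),
            ("EtOAc", E.SOLVENT),
            ("washed", E.WORKUP),
            ("NH4Cl", E.OTHER_COMPOUND),
        ],
    )
    # simulate the faulty segmentation the rule exists to repair
    cut = text.index("NH4Cl")
    doc.sentences = [(0, cut - 1), (cut, len(text))]
    traces = []
    merge_satag_and_link(doc, traces)
    assert doc.sentences == [(0, len(text))]
    assert len(doc.relations) == 1
    rel = doc.relations[0]
    assert rel.argument.surface == "NH4Cl" and rel.label is RelationLabel.ARG1
    assert rel.trigger.surface == "washed"  # nearest preceding trigger
    assert any(t.action.get("op") == "merge_sentences" for t in traces)


def test_satag_clause_head_strategy_matches_first_trigger(doc_factory):
    text = ("the residue was dissolved in EtOAc and washed with sat. aq. "
            "NH4Cl")
    doc = doc_factory(
        text,
        [
            ("dissolved", E.WORKUP),
            ("EtOAc", E.SOLVENT),
            ("washed", E.WORKUP),
            ("NH4Cl", E.OTHER_COMPOUND),
        ],
    )
    merge_satag_and_link(doc, strategy="clause-head")
    assert doc.relations[0].trigger.surface == "dissolved"


def test_satag_link_applies_inside_guarded_sentence(doc_factory):
    # the guarded segmenter keeps the clause whole; linking still applies
    doc = doc_factory(
        "the residue was dissolved in EtOAc and washed with sat. aq. NH4Cl",
        [
            ("dissolved", E.WORKUP),
            ("EtOAc", E.SOLVENT),
            ("washed", E.WORKUP),
            ("NH4Cl", E.OTHER_COMPOUND),
        ],
    )
    assert len(doc.sentences) == 1
    merge_satag_and_link(doc)
    assert [r.argument.surface for r in doc.relations] == ["NH4Cl"]


def test_merge_satag_without_phrase_is_noop(doc_factory):
    doc = doc_factory(
        "the residue was dissolved in EtOAc.",
        [("dissolved", E.WORKUP), ("EtOAc", E.SOLVENT)],
    )
    before = copy.deepcopy(doc.sentences)
    merge_satag_and_link(doc)
    assert doc.sentences == before and doc.relations == []


def test_yield_sentence_links_to_previous_trigger(doc_factory):
    text = ("The mixture is purified by RP-HPLC (modifier: ammonium "
            "hydroxide). Yield: 15 mg (25% of theory).")
    doc = doc_factory(
        text,
        [
            ("purified", E.WORKUP),
            ("15 mg", E.YIELD_OTHER),
            ("25%", E.YIELD_PERCENT),
        ],
    )
    traces = []
    link_yield_sentence(doc, traces)
    assert len(doc.relations) == 2
    for rel in doc.relations:
        assert rel.label is RelationLabel.ARGM
        assert rel.trigger.surface == "purified"
    assert sorted(r.argument.surface for r in doc.relations) == ["15 mg", "25%"]


def test_yield_sentence_without_previous_trigger_warns(doc_factory):
    text = "The mixture stood. Yield: 15 mg (25% of theory)."
    doc = doc_factory(
        text, [("15 mg", E.YIELD_OTHER), ("25%", E.YIELD_PERCENT)]
    )
    traces = []
    link_yield_sentence(doc, traces)
    assert doc.relations == []
    assert any("warning" in t.after for t in traces)


def test_yield_sentence_first_in_document_warns(doc_factory):
    doc = doc_factory("Yield: 15 mg (25% of theory).",
                      [("15 mg", E.YIELD_OTHER), ("25%", E.YIELD_PERCENT)])
    traces = []
    link_yield_sentence(doc, traces)
    assert doc.relations == [] and any("warning" in t.after for t in traces)


def test_rules_are_idempotent_on_pipeline_output(trained_small_pipeline):
    pipe, _, test = trained_small_pipeline
    preds = predict_corpus(pipe, test, RuleConfig())
    for doc in preds:
        once = copy.deepcopy(doc)
        twice, traces = apply_all_rules(copy.deepcopy(doc), RuleConfig())
        assert [m.key() for m in twice.entities] == [
            m.key() for m in once.entities
        ]
        assert sorted(r.key() for r in twice.relations) == sorted(
            r.key() for r in once.relations
        )
        assert twice.sentences == once.sentences


def test_rule_outputs_satisfy_mention_invariants(trained_small_pipeline):
    pipe, _, test = trained_small_pipeline
    for doc in predict_corpus(pipe, test, RuleConfig()):
        doc.validate()


def test_trace_replay_reproduces_rule_effects(doc_factory):
    text = ("EXAMPLE 48\n"
            "Synthesis of 2-bromoaniline\n"
            "48.1 7-fluoroquinoline\n"
            "The mixture was purified by HPLC. Yield: 15 mg (25% of theory).")
    doc = doc_factory(
        text,
        [
            ("Example 48".replace("Example", "EXAMPLE"), E.EXAMPLE_LABEL),
            ("2-bromoaniline", E.REACTION_PRODUCT),
            ("7-fluoroquinoline", E.OTHER_COMPOUND),
            ("purified", E.WORKUP),
            ("15 mg", E.YIELD_OTHER),
            ("25%", E.YIELD_PERCENT),
        ],
    )
    pristine = copy.deepcopy(doc)
    out, traces = apply_all_rules(doc, RuleConfig())
    assert traces  # something happened
    replayed = replay_traces(pristine, traces)
    assert [m.key() for m in replayed.entities] == [
        m.key() for m in out.entities
    ]
    assert sorted(r.key() for r in replayed.relations) == sorted(
        r.key() for r in out.relations
    )
    assert replayed.sentences == out.sentences
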