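import copy
import json
import random

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from chemrext.evaluation import (
    Counts,
    match_entities,
    match_relations,
    score,
)
from chemrext.standoff import (
    ContractError,
    Document,
    EntityLabel,
    EntityMention,
    RelationLabel,
    RelationMention,
)

E = EntityLabel


def _m(eid, label, start, end):
    return EntityMention(eid, label, start, end, "x" * (end - start))


def test_counts_reproduce_precision_recall_f1_definitions():
    c = Counts(tp=2, fp=1, fn=1)
    assert c.precision == pytest.approx(2 / 3)
    assert c.recall == pytest.approx(2 / 3)
    assert c.f1 == pytest.approx(2 / 3)


def test_zero_denominator_convention():
    assert Counts().precision == 0.0
    assert Counts().recall == 0.0
    assert Counts().f1 == 0.0
    assert Counts(tp=0, fp=3, fn=0).precision == 0.0


def test_identical_sets_are_all_true_positives():
    gold = [_m("T1", E.TIME, 0, 3), _m("T2", E.SOLVENT, 5, 10)]
    counts = match_entities(gold, copy.deepcopy(gold), "exact")
    assert counts["TIME"].tp == 1 and counts["SOLVENT"].tp == 1
    assert all(c.fp == c.fn == 0 for c in counts.values())


def test_boundary_error_exact_vs_relaxed():
    gold = [_m("T1", E.TIME, 0, 6)]
    pred = [_m("T1", E.TIME, 0, 5)]
    exact = match_entities(gold, pred, "exact")["TIME"]
    assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
    relaxed = match_entities(gold, pred, "relaxed")["TIME"]
    assert (relaxed.tp, relaxed.fp, relaxed.fn) == (1, 0, 0)


def test_wrong_label_fails_in_both_modes():
    gold = [_m("T1", E.TIME, 0, 6)]
    pred = [_m("T1", E.TEMPERATURE, 0, 6)]
    for mode in ("exact", "relaxed"):
        counts = match_entities(gold, pred, mode)
        assert counts["TIME"].fn == 1
        assert counts["TEMPERATURE"].fp == 1


def _rel(rid, label, trigger, argument):
    return RelationMention(rid, label, trigger, argument)


def test_relation_label_mismatch_counts_fp_and_fn():
    trig = _m("T1", E.REACTION_STEP, 0, 7)
    arg_sol = _m("T2", E.SOLVENT, 10, 14)
    gold = [_rel("R1", RelationLabel.ARG1, trig, arg_sol)]
    # same endpoints, ARG1 vs ARGM
    pred = [_rel("R1", RelationLabel.ARGM, copy.deepcopy(trig),
                 copy.deepcopy(arg_sol))]
    for mode in ("exact", "relaxed"):
        counts = match_relations(gold, pred, mode)
        assert sum(c.tp for c in counts.values()) == 0
        assert sum(c.fp for c in counts.values()) == 1
        assert sum(c.fn for c in counts.values()) == 1
    # argument entity type mismatch also fails
    pred_wrong_arg = [_rel("R1", RelationLabel.ARG1, copy.deepcopy(trig),
                           _m("T2", E.OTHER_COMPOUND, 10, 14))]
    counts = match_relations(gold, pred_wrong_arg, "exact")
    assert sum(c.fp for c in counts.values()) == 1
    assert sum(c.fn for c in counts.values()) == 1


def test_relation_endpoint_matching_inherits_entity_mode():
    trig_g = _m("T1", E.REACTION_STEP, 0, 7)
    trig_p = _m("T1", E.REACTION_STEP, 0, 6)  # off by one character
    arg = _m("T2", E.TIME, 10, 13)
    gold = [_rel("R1", RelationLabel.ARGM, trig_g, arg)]
    pred = [_rel("R1", RelationLabel.ARGM, trig_p, copy.deepcopy(arg))]
    exact = match_relations(gold, pred, "exact")
    assert sum(c.tp for c in exact.values()) == 0
    relaxed = match_relations(gold, pred, "relaxed")
    assert sum(c.tp for c in relaxed.values()) == 1


def _doc(doc_id, entities, relations=()):
    return Document(doc_id=doc_id, text="x" * 200, entities=list(entities),
                    relations=list(relations))


def test_score_direct_substitution():
    gold = [_doc("d", [_m("T1", E.TIME, 0, 3), _m("T2", E.TIME, 5, 8),
                       _m("T3", E.TIME, 10, 13)])]
    pred = [_doc("d", [_m("T1", E.TIME, 0, 3), _m("T2", E.TIME, 5, 8),
                       _m("T3", E.TIME, 20, 23)])]
    report = score(gold, pred, task="ner", mode="exact")
    overall = report.overall
    assert (overall.tp, overall.fp, overall.fn) == (2, 1, 1)
    assert overall.precision == pytest.approx(2 / 3)
    assert overall.recall == pytest.approx(2 / 3)
    assert overall.f1 == pytest.approx(2 / 3)


def test_empty_prediction_scores_zero():
    gold = [_doc("d", [_m("T1", E.TIME, 0, 3)])]
    pred = [_doc("d", [])]
    overall = score(gold, pred).overall
    assert overall.precision == overall.recall == overall.f1 == 0.0


def test_gold_vs_gold_is_perfect_on_synthetic_corpus(small_corpus):
    docs = small_corpus[:10]
    for task in ("ner", "relation"):
        for mode in ("exact", "relaxed"):
            report = score(docs, docs, task=task, mode=mode)
            assert report.overall.f1 == 1.0


def test_document_id_mismatch_is_contract_error():
    with pytest.raises(ContractError):
        score([_doc("a", [])], [_doc("b", [])])


def test_metrics_invariant_to_document_order(small_corpus):
    docs = small_corpus[:8]
    preds = [copy.deepcopy(d) for d in docs]
    preds[0].entities = preds[0].entities[:-1]
    r1 = score(docs, preds)
    r2 = score(list(reversed(docs)), preds)
    assert r1.to_dict() == r2.to_dict()


def test_report_rows_sum_to_overall(small_corpus):
    docs = small_corpus[:8]
    preds = [copy.deepcopy(d) for d in docs]
    preds[1].entities = preds[1].entities[1:]
    report = score(docs, preds)
    data = report.to_dict()["scores"]
    assert sum(v["tp"] for k, v in data.items() if k != "Overall") == \
        data["Overall"]["tp"]
    json.loads(report.to_json())  # report serializes to valid JSON
    assert "Overall" in report.to_text()


# ---------------------------------------------------------------------------
# oracle comparison: greedy one-to-one matching vs maximum bipartite matching


def oracle_tp(gold, pred, mode):
    """Maximum bipartite matching size over the compatibility graph."""
    if not gold or not pred:
        return 0
    rows = []
    for g in gold:
        row = []
        for p in pred:
            if g.label != p.label:
                row.append(0)
            elif mode == "exact":
                row.append(int((g.start, g.end) == (p.start, p.end)))
            else:
                row.append(
                    int(min(g.end, p.end) - max(g.start, p.start) > 0)
                )
        rows.append(row)
    graph = csr_matrix(np.array(rows))
    matching = maximum_bipartite_matching(graph, perm_type="column")
    return int((matching >= 0).sum())


def random_matching_case(rng):
    """Non-overlapping gold; predictions perturb gold or fall in gaps."""
    gold, pred = [], []
    pos = 0
    labels = [E.TIME, E.SOLVENT, E.OTHER_COMPOUND]
    for i in range(rng.randint(1, 8)):
        start = pos + rng.randint(2, 5)
        end = start + rng.randint(2, 6)
        pos = end + 2  # keep a gap so perturbed spans stay local
        label = rng.choice(labels)
        gold.append(_m(f"G{i}", label, start, end))
        roll = rng.random()
        if roll < 0.6:  # perturbed copy (possibly exact)
            ds = rng.choice([-1, 0, 0, 1])
            de = rng.choice([-1, 0, 0, 1])
            ps, pe = start + ds, end + de
            if ps < pe:
                plabel = label if rng.random() < 0.8 else rng.choice(labels)
                pred.append(_m(f"P{i}", plabel, ps, pe))
        elif roll < 0.8:  # spurious mention in the following gap
            pred.append(_m(f"P{i}", rng.choice(labels), end + 1, end + 2))
    return gold, pred


@pytest.mark.parametrize("mode", ["exact", "relaxed"])
def test_greedy_matching_agrees_with_bipartite_oracle(mode):
    rng = random.Random(2024)
    for _ in range(300):
        gold, pred = random_matching_case(rng)
        counts = match_entities(gold, pred, mode)
        greedy_tp = sum(c.tp for c in counts.values())
        assert greedy_tp == oracle_tp(gold, pred, mode)


def test_relaxed_f1_dominates_exact_f1(trained_small_pipeline):
    from chemrext.pipeline import predict_corpus
    from chemrext.rules import RuleConfig

    pipe, _, test = trained_small_pipeline
    preds = predict_corpus(pipe, test, RuleConfig())
    for task in ("ner", "end_to_end"):
        exact = score(test, preds, task=task, mode="exact").overall
        relaxed = score(test, preds, task=task, mode="relaxed").overall
        assert relaxed.tp >= exact.tp
        assert relaxed.f1 >= exact.f1
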