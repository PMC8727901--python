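"""Exact and relaxed scoring of entities and relations.

precision = TP / (TP + FP), recall = TP / (TP + FN),
F1 = 2 * precision * recall / (precision + recall),
with the zero-denominator convention that all three are 0.

Exact matching requires identical label and identical character span; relaxed
matching requires identical label and character-span overlap of at least one
code point.  Matching is one-to-one, resolved greedily by largest overlap and
then earliest span — near-optimal in practice and checked against a maximum
bipartite matching oracle in the test suite.  Relation matching requires equal
relation labels and both endpoint entities matching under the chosen entity
mode; relation counts are grouped by "LABEL|TRIGGER_TYPE|ARGUMENT_TYPE" keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .standoff import ContractError, Document, EntityMention, RelationMention

MODES = ("exact", "relaxed")
TASKS = ("ner", "relation", "end_to_end")

OVERALL = "Overall"


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __iadd__(self, other: "Counts") -> "Counts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def _overlap(a: EntityMention, b: EntityMention) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _entity_match(gold: EntityMention, pred: EntityMention, mode: str) -> bool:
    if gold.label != pred.label:
        return False
    if mode == "exact":
        return gold.start == pred.start and gold.end == pred.end
    return _overlap(gold, pred) > 0


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ContractError(f"unknown matching mode {mode!r}")


def _greedy_pairs(
    gold: Sequence, pred: Sequence, compatible, weight
) -> list[tuple[int, int]]:
    """One-to-one matching, greedy by descending weight then earliest spans."""
    candidates = [
        (gi, pi)
        for gi, g in enumerate(gold)
        for pi, p in enumerate(pred)
        if compatible(g, p)
    ]
    candidates.sort(key=lambda gp: (-weight(gold[gp[0]], pred[gp[1]]), gp))
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        pairs.append((gi, pi))
    return pairs


def match_entities(
    gold: Sequence[EntityMention],
    pred: Sequence[EntityMention],
    mode: str = "exact",
) -> dict[str, Counts]:
    """Per-label TP/FP/FN from one-to-one span matching."""
    _check_mode(mode)
    gold = sorted(gold, key=lambda m: (m.start, m.end, m.label.value))
    pred = sorted(pred, key=lambda m: (m.start, m.end, m.label.value))
    pairs = _greedy_pairs(
        gold, pred,
        compatible=lambda g, p: _entity_match(g, p, mode),
        weight=_overlap,
    )
    counts: dict[str, Counts] = {}
    matched_g = {gi for gi, _ in pairs}
    matched_p = {pi for _, pi in pairs}
    for gi, _ in pairs:
        counts.setdefault(gold[gi].label.value, Counts()).tp += 1
    for gi, g in enumerate(gold):
        if gi not in matched_g:
            counts.setdefault(g.label.value, Counts()).fn += 1
    for pi, p in enumerate(pred):
        if pi not in matched_p:
            counts.setdefault(p.label.value, Counts()).fp += 1
    return counts


def relation_type_key(rel: RelationMention) -> str:
    return "|".join(
        [rel.label.value, rel.trigger.label.value, rel.argument.label.value]
    )


def _relation_match(gold: RelationMention, pred: RelationMention,
                    mode: str) -> bool:
    return (
        gold.label == pred.label
        and _entity_match(gold.trigger, pred.trigger, mode)
        and _entity_match(gold.argument, pred.argument, mode)
    )


def match_relations(
    gold: Sequence[RelationMention],
    pred: Sequence[RelationMention],
    mode: str = "exact",
) -> dict[str, Counts]:
    """Per-relation-type TP/FP/FN; endpoint matching inherits the entity mode."""
    _check_mode(mode)
    gold = sorted(gold, key=lambda r: (r.trigger.start, r.argument.start, r.id))
    pred = sorted(pred, key=lambda r: (r.trigger.start, r.argument.start, r.id))
    pairs = _greedy_pairs(
        gold, pred,
        compatible=lambda g, p: _relation_match(g, p, mode),
        weight=lambda g, p: (
            _overlap(g.trigger, p.trigger) + _overlap(g.argument, p.argument)
        ),
    )
    counts: dict[str, Counts] = {}
    matched_g = {gi for gi, _ in pairs}
    matched_p = {pi for _, pi in pairs}
    for gi, _ in pairs:
        counts.setdefault(relation_type_key(gold[gi]), Counts()).tp += 1
    for gi, g in enumerate(gold):
        if gi not in matched_g:
            counts.setdefault(relation_type_key(g), Counts()).fn += 1
    for pi, p in enumerate(pred):
        if pi not in matched_p:
            counts.setdefault(relation_type_key(p), Counts()).fp += 1
    return counts


@dataclass
class EvalReport:
    """Per-label and overall precision/recall/F1 for one task and mode."""

    task: str
    mode: str
    per_label: dict[str, Counts] = field(default_factory=dict)

    @property
    def overall(self) -> Counts:
        total = Counts()
        for c in self.per_label.values():
            total += Counts(c.tp, c.fp, c.fn)
        return total

    def to_dict(self) -> dict:
        def row(c: Counts) -> dict:
            return {
                "tp": c.tp, "fp": c.fp, "fn": c.fn,
                "precision": round(c.precision, 6),
                "recall": round(c.recall, 6),
                "f1": round(c.f1, 6),
            }

        body = {label: row(c) for label, c in sorted(self.per_label.items())}
        body[OVERALL] = row(self.overall)
        return {"task": self.task, "mode": self.mode, "scores": body}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        rows = list(sorted(self.per_label.items())) + [(OVERALL, self.overall)]
        width = max(len(name) for name, _ in rows)
        lines = [
            f"{self.task} / {self.mode} matching",
            f"{'type'.ljust(width)}  {'P':>7} {'R':>7} {'F1':>7} "
            f"{'TP':>5} {'FP':>5} {'FN':>5}",
        ]
        for name, c in rows:
            lines.append(
                f"{name.ljust(width)}  {c.precision:7.4f} {c.recall:7.4f} "
                f"{c.f1:7.4f} {c.tp:5d} {c.fp:5d} {c.fn:5d}"
            )
        return "\n".join(lines)


def _merge(into: dict[str, Counts], part: dict[str, Counts]) -> None:
    for key, c in part.items():
        into.setdefault(key, Counts()).__iadd__(c)


def score(
    gold_docs: Iterable[Document],
    pred_docs: Iterable[Document],
    task: str = "ner",
    mode: str = "exact",
) -> EvalReport:
    """Aggregate matching counts over aligned documents, then compute metrics.

    For ``task="ner"`` entities are scored; for ``"relation"`` and
    ``"end_to_end"`` relations are scored (the two differ only in whether the
    predicted documents carry gold or pipeline-predicted entities).
    """
    _check_mode(mode)
    if task not in TASKS:
        raise ContractError(f"unknown task {task!r}")
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(gold_by_id) != set(pred_by_id):
        raise ContractError(
            "gold and predicted document ids do not align one-to-one"
        )
    report = EvalReport(task=task, mode=mode)
    for doc_id in sorted(gold_by_id):
        g, p = gold_by_id[doc_id], pred_by_id[doc_id]
        if task == "ner":
            _merge(report.per_label, match_entities(g.entities, p.entities, mode))
        else:
            _merge(report.per_label,
                   match_relations(g.relations, p.relations, mode))
    return report
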