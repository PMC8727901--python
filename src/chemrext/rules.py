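"""Deterministic postprocessing rules.

NER repairs: relabel compounds in example headings by document structure, trim
lead words and brackets from EXAMPLE_LABEL spans, trim "compound"/"example"
prefixes from numerically-identified chemicals.  Relation recovery: re-merge
sentences wrongly split at "sat. aq." and link the following chemical to an
event trigger, and link "Yield: ..." sentences back to the trigger of the
previous sentence.  Every modification emits one RuleTrace carrying a
machine-replayable action, and the full rule set is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .relations import assign_relation_label
from .standoff import (
    ARG1_ROLES,
    ContractError,
    Document,
    EntityLabel,
    EntityMention,
    RelationMention,
    is_trigger,
)

_BRACKETS = "()[]{}"
#: Lead words stripped from EXAMPLE_LABEL spans ("reference example" first so
#: the two-word form wins over the bare "example").
_EXAMPLE_LEAD_WORDS = ("reference example", "example", "step", "intermediate",
                       "core")
_COMPOUND_LEAD_WORDS = ("compound", "example", "immediate")
#: Numeric or mixed number-letter identifier, e.g. "1-0003", "56A", "95".
_NUMERIC_ID_RE = re.compile(r"[0-9][0-9A-Za-z-]*")
_COMPOUND_ROLES = ARG1_ROLES
_HEADING_RE = re.compile(r"^\s*(?:EXAMPLE|Example|STEP|Step)\s+\S+\s*$")
_SUBSTEP_RE = re.compile(r"^\s*\d+\.\d+\b")
_YIELD_RE = re.compile(r"^\s*Yield\s*:", re.IGNORECASE)
_SATAG_RE = re.compile(r"sat\.\s+aq\.")


@dataclass
class RuleTrace:
    """Audit record for one rule application.

    ``action`` is machine-readable and sufficient to replay the modification;
    ``before``/``after`` are human-readable descriptions ("created"/"deleted"
    for mention creation/removal, "warning: ..." when a rule declined to act).
    """

    rule_name: str
    doc_id: str
    before: str
    after: str
    action: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        return "\t".join([self.rule_name, self.doc_id, self.before, self.after])


@dataclass
class RuleConfig:
    relabel_headings: bool = True
    trim_example: bool = True
    trim_compound: bool = True
    merge_satag: bool = True
    link_yield: bool = True
    #: how merge_satag_and_link picks the trigger: "nearest" preceding trigger
    #: by token distance, or "clause-head" (first trigger of the clause).
    satag_strategy: str = "nearest"


def _describe(ent: EntityMention) -> str:
    return f"{ent.id} {ent.label.value} [{ent.start},{ent.end}) {ent.surface!r}"


def _shrunk(entity: EntityMention, text: str) -> tuple[int, int, bool]:
    """New offsets after lead-word/bracket trimming; flag=False if emptied."""
    start, end = entity.start, entity.end
    changed = True
    while changed and start < end:
        changed = False
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if start < end and text[start] in _BRACKETS:
            start += 1
            changed = True
        if start < end and text[end - 1] in _BRACKETS:
            end -= 1
            changed = True
        seg = text[start:end].lower()
        for word in _EXAMPLE_LEAD_WORDS:
            if seg.startswith(word) and (
                len(seg) == len(word) or not seg[len(word)].isalnum()
            ):
                start += len(word)
                changed = True
                break
    while start < end and text[start].isspace():
        start += 1
    return start, end, start < end


def trim_example_label(entity: EntityMention, text: str) -> EntityMention:
    """Strip lead words ("example", "step", ...) and brackets from an
    EXAMPLE_LABEL span by shrinking its offsets; no-op if nothing matches or
    trimming would empty the span."""
    if entity.label is not EntityLabel.EXAMPLE_LABEL:
        raise ContractError("trim_example_label applies to EXAMPLE_LABEL only")
    start, end, ok = _shrunk(entity, text)
    if not ok or (start, end) == (entity.start, entity.end):
        return entity
    return EntityMention(entity.id, entity.label, start, end, text[start:end])


def trim_compound_prefix(entity: EntityMention, text: str) -> EntityMention:
    """Strip "compound"/"example"/"immediate" from chemical mentions whose
    remainder is a numeric or mixed number-letter identifier."""
    if entity.label not in _COMPOUND_ROLES:
        return entity
    surface = entity.surface
    low = surface.lower()
    for word in _COMPOUND_LEAD_WORDS:
        if not low.startswith(word):
            continue
        rest = surface[len(word):]
        stripped = rest.lstrip()
        if rest == stripped:  # lead word not followed by a separator
            continue
        if _NUMERIC_ID_RE.fullmatch(stripped):
            start = entity.start + len(surface) - len(stripped)
            return EntityMention(
                entity.id, entity.label, start, entity.end, text[start:entity.end]
            )
    return entity


def _line_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    start = 0
    for i, ch in enumerate(text):
        if ch == "\n":
            spans.append((start, i))
            start = i + 1
    spans.append((start, len(text)))
    return spans


def relabel_heading_compounds(
    doc: Document, traces: list[RuleTrace] | None = None
) -> Document:
    """Distinguish product vs. other compounds by heading structure.

    When a top-level example heading is followed by a sub-step heading
    ("<n>.<m> ..."), the snippet describes the sub-step: compound mentions in
    the top-level heading region become OTHER_COMPOUND, and compounds on the
    sub-step heading line carry the REACTION_PRODUCT label.
    """
    lines = _line_spans(doc.text)
    top_start = None
    sub_span = None
    for s, e in lines:
        line = doc.text[s:e]
        if top_start is None and _HEADING_RE.match(line):
            top_start = s
        elif top_start is not None and _SUBSTEP_RE.match(line):
            sub_span = (s, e)
            break
    if top_start is None or sub_span is None:
        return doc
    for ent in doc.entities:
        if ent.label not in (EntityLabel.REACTION_PRODUCT,
                             EntityLabel.OTHER_COMPOUND):
            continue
        in_top = top_start <= ent.start and ent.end <= sub_span[0]
        in_sub = sub_span[0] <= ent.start and ent.end <= sub_span[1]
        new = None
        if in_top and ent.label is EntityLabel.REACTION_PRODUCT:
            new = EntityLabel.OTHER_COMPOUND
        elif in_sub and ent.label is EntityLabel.OTHER_COMPOUND:
            new = EntityLabel.REACTION_PRODUCT
        if new is not None:
            before = _describe(ent)
            ent.label = new
            if traces is not None:
                traces.append(
                    RuleTrace(
                        "relabel_heading_compounds", doc.doc_id, before,
                        _describe(ent),
                        {"op": "relabel", "id": ent.id, "label": new.value},
                    )
                )
    return doc


def _relation_exists(doc: Document, trigger: EntityMention,
                     argument: EntityMention) -> bool:
    return any(
        rel.trigger.key() == trigger.key()
        and rel.argument.key() == argument.key()
        for rel in doc.relations
    )


def _next_relation_id(doc: Document) -> str:
    used = {rel.id for rel in doc.relations}
    i = len(doc.relations) + 1
    while f"R{i}" in used:
        i += 1
    return f"R{i}"


def _create_relation(
    doc: Document,
    trigger: EntityMention,
    argument: EntityMention,
    rule_name: str,
    traces: list[RuleTrace] | None,
) -> None:
    label = assign_relation_label(trigger.label, argument.label)
    rel = RelationMention(_next_relation_id(doc), label, trigger, argument)
    doc.relations.append(rel)
    if traces is not None:
        traces.append(
            RuleTrace(
                rule_name, doc.doc_id,
                f"{label.value} {trigger.surface!r} -> {argument.surface!r}",
                "created",
                {"op": "create_relation", "trigger": trigger.id,
                 "argument": argument.id, "label": label.value},
            )
        )


def merge_satag_and_link(
    doc: Document,
    traces: list[RuleTrace] | None = None,
    strategy: str = "nearest",
) -> Document:
    """Repair "sat. aq." segmentation splits and recover the lost relation.

    If a sentence ends with "sat. aq." and the next one begins with a chemical
    mention, the two sentence spans are merged.  Then, for every "sat. aq."
    occurrence followed by a chemical mention inside one sentence, a relation
    is created from an event trigger earlier in the clause to that chemical
    (unless one already exists).  ``strategy`` selects the trigger: "nearest"
    preceding trigger by token distance, or "clause-head" for the first
    trigger of the clause.
    """
    if strategy not in ("nearest", "clause-head"):
        raise ContractError(f"unknown satag strategy {strategy!r}")
    # -- merge wrongly split sentences
    merged = True
    while merged:
        merged = False
        for i in range(len(doc.sentences) - 1):
            s, e = doc.sentences[i]
            if not doc.text[s:e].rstrip().endswith("sat. aq."):
                continue
            ns, ne = doc.sentences[i + 1]
            starts_with_chem = any(
                m.start == ns and m.label in _COMPOUND_ROLES
                for m in doc.entities
            )
            if not starts_with_chem:
                continue
            doc.sentences[i : i + 2] = [(s, ne)]
            if traces is not None:
                traces.append(
                    RuleTrace(
                        "merge_satag_and_link", doc.doc_id,
                        f"sentences [{s},{e}) + [{ns},{ne})",
                        f"merged [{s},{ne})",
                        {"op": "merge_sentences", "index": i},
                    )
                )
            merged = True
            break
    # -- link the chemical behind "sat. aq." to a trigger in the clause
    for s, e in doc.sentences:
        for m in _SATAG_RE.finditer(doc.text[s:e]):
            occ_end = s + m.end()
            chems = [
                ent
                for ent in doc.entities_in_span(occ_end, e)
                if ent.label in _COMPOUND_ROLES
            ]
            if not chems:
                continue
            chem = chems[0]
            triggers = [
                ent
                for ent in doc.entities_in_span(s, s + m.start())
                if is_trigger(ent.label)
            ]
            if not triggers:
                continue
            trigger = triggers[-1] if strategy == "nearest" else triggers[0]
            already_linked = any(
                rel.argument.key() == chem.key() for rel in doc.relations
            )
            if not already_linked:
                _create_relation(doc, trigger, chem, "merge_satag_and_link",
                                 traces)
    return doc


def link_yield_sentence(
    doc: Document, traces: list[RuleTrace] | None = None
) -> Document:
    """Link yield mentions in a separate "Yield: ..." sentence to the last
    event trigger of the previous sentence with ARGM relations."""
    for i, (s, e) in enumerate(doc.sentences):
        if not _YIELD_RE.match(doc.text[s:e]):
            continue
        yields = [
            ent
            for ent in doc.entities_in_span(s, e)
            if ent.label in (EntityLabel.YIELD_OTHER, EntityLabel.YIELD_PERCENT)
        ]
        if not yields:
            continue
        if i == 0:
            if traces is not None:
                traces.append(
                    RuleTrace(
                        "link_yield_sentence", doc.doc_id,
                        f"yield sentence [{s},{e})",
                        "warning: no previous sentence", {},
                    )
                )
            continue
        ps, pe = doc.sentences[i - 1]
        triggers = [
            ent for ent in doc.entities_in_span(ps, pe) if is_trigger(ent.label)
        ]
        if not triggers:
            if traces is not None:
                traces.append(
                    RuleTrace(
                        "link_yield_sentence", doc.doc_id,
                        f"yield sentence [{s},{e})",
                        "warning: previous sentence has no trigger", {},
                    )
                )
            continue
        trigger = triggers[-1]
        for ym in yields:
            if not _relation_exists(doc, trigger, ym):
                _create_relation(doc, trigger, ym, "link_yield_sentence", traces)
    return doc


def apply_ner_rules(
    doc: Document, config: RuleConfig | None = None
) -> tuple[Document, list[RuleTrace]]:
    """NER postprocessing: heading relabeling, then span trims."""
    config = config or RuleConfig()
    traces: list[RuleTrace] = []
    if config.relabel_headings:
        relabel_heading_compounds(doc, traces)
    for idx, ent in enumerate(doc.entities):
        new = ent
        if config.trim_example and ent.label is EntityLabel.EXAMPLE_LABEL:
            rule = "trim_example_label"
            new = trim_example_label(ent, doc.text)
            start, end, ok = _shrunk(ent, doc.text)
            if not ok and (start, end) != (ent.start, ent.end):
                traces.append(
                    RuleTrace(rule, doc.doc_id, _describe(ent),
                              "warning: trim would empty span", {})
                )
        elif config.trim_compound and ent.label in _COMPOUND_ROLES:
            rule = "trim_compound_prefix"
            new = trim_compound_prefix(ent, doc.text)
        else:
            continue
        if (new.start, new.end) != (ent.start, ent.end):
            traces.append(
                RuleTrace(
                    rule, doc.doc_id, _describe(ent), _describe(new),
                    {"op": "trim", "id": ent.id, "start": new.start,
                     "end": new.end},
                )
            )
            # mutate in place so relations keep referencing the same object
            ent.start, ent.end, ent.surface = new.start, new.end, new.surface
    return doc, traces


def apply_relation_rules(
    doc: Document, config: RuleConfig | None = None
) -> tuple[Document, list[RuleTrace]]:
    """Cross-sentence relation recovery: sat.-aq. merge, then yield linking."""
    config = config or RuleConfig()
    traces: list[RuleTrace] = []
    if config.merge_satag:
        merge_satag_and_link(doc, traces, strategy=config.satag_strategy)
    if config.link_yield:
        link_yield_sentence(doc, traces)
    return doc, traces


def apply_all_rules(
    doc: Document, config: RuleConfig | None = None
) -> tuple[Document, list[RuleTrace]]:
    doc, ner_traces = apply_ner_rules(doc, config)
    doc, rel_traces = apply_relation_rules(doc, config)
    return doc, ner_traces + rel_traces


def replay_traces(doc: Document, traces: Sequence[RuleTrace]) -> Document:
    """Re-apply the machine-readable actions of a trace list to ``doc``."""
    for trace in traces:
        action = trace.action
        op = action.get("op")
        if op == "relabel":
            ent = doc.entity_by_id(action["id"])
            ent.label = EntityLabel(action["label"])
        elif op == "trim":
            ent = doc.entity_by_id(action["id"])
            start, end = action["start"], action["end"]
            ent.start, ent.end = start, end
            ent.surface = doc.text[start:end]
        elif op == "merge_sentences":
            i = action["index"]
            (s, _), (_, ne) = doc.sentences[i], doc.sentences[i + 1]
            doc.sentences[i : i + 2] = [(s, ne)]
        elif op == "create_relation":
            trigger = doc.entity_by_id(action["trigger"])
            argument = doc.entity_by_id(action["argument"])
            if not _relation_exists(doc, trigger, argument):
                _create_relation(doc, trigger, argument, trace.rule_name, None)
    return doc
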