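"""Document model and BRAT-style standoff annotation I/O.

A patent snippet is stored as a ``.txt`` file plus a ``.ann`` file holding
entity lines (``T<i>\\tLABEL start end\\tsurface``) and relation lines
(``R<i>\\tLABEL Arg1:T<j> Arg2:T<k>``).  Offsets are 0-based, half-open and
counted in Unicode code points.  In a relation line the ``Arg1:`` slot always
carries the event trigger and ``Arg2:`` the semantic-role argument.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .preprocess import Token


class StandoffParseError(ValueError):
    """A standoff line does not parse; the message names the line number."""


class AnnotationIntegrityError(ValueError):
    """Annotations are inconsistent with the text or with the schema."""


class ContractError(ValueError):
    """An operation was called outside its contract."""


class EntityLabel(str, enum.Enum):
    """The 12 mention types: 10 semantic roles followed by 2 event triggers."""

    EXAMPLE_LABEL = "EXAMPLE_LABEL"
    STARTING_MATERIAL = "STARTING_MATERIAL"
    REAGENT_CATALYST = "REAGENT_CATALYST"
    REACTION_PRODUCT = "REACTION_PRODUCT"
    SOLVENT = "SOLVENT"
    TIME = "TIME"
    TEMPERATURE = "TEMPERATURE"
    YIELD_PERCENT = "YIELD_PERCENT"
    YIELD_OTHER = "YIELD_OTHER"
    OTHER_COMPOUND = "OTHER_COMPOUND"
    REACTION_STEP = "REACTION_STEP"
    WORKUP = "WORKUP"


#: Accepted alternative spellings of the trigger labels.
_LABEL_ALIASES = {
    "REACTION_SETUP": EntityLabel.REACTION_STEP,
    "WORK_UP": EntityLabel.WORKUP,
}

TRIGGER_LABELS = frozenset({EntityLabel.REACTION_STEP, EntityLabel.WORKUP})
ROLE_LABELS = frozenset(EntityLabel) - TRIGGER_LABELS

#: Roles a trigger may govern through an ARG1 (compound) relation.
ARG1_ROLES = frozenset(
    {
        EntityLabel.STARTING_MATERIAL,
        EntityLabel.REAGENT_CATALYST,
        EntityLabel.REACTION_PRODUCT,
        EntityLabel.SOLVENT,
        EntityLabel.OTHER_COMPOUND,
    }
)

#: Roles governed through an ARGM (auxiliary: time/temperature/yield) relation.
ARGM_ROLES = frozenset(
    {
        EntityLabel.TIME,
        EntityLabel.TEMPERATURE,
        EntityLabel.YIELD_OTHER,
        EntityLabel.YIELD_PERCENT,
    }
)


def is_trigger(label: EntityLabel) -> bool:
    return label in TRIGGER_LABELS


def parse_entity_label(name: str) -> EntityLabel:
    name = name.strip()
    if name in _LABEL_ALIASES:
        return _LABEL_ALIASES[name]
    try:
        return EntityLabel(name)
    except ValueError:
        raise StandoffParseError(f"unknown entity label {name!r}") from None


class RelationLabel(str, enum.Enum):
    ARG1 = "ARG1"
    ARGM = "ARGM"


@dataclass
class EntityMention:
    """A typed contiguous span anchored to document character offsets."""

    id: str
    label: EntityLabel
    start: int
    end: int
    surface: str

    def validate(self, text: str) -> None:
        if not (0 <= self.start < self.end <= len(text)):
            raise AnnotationIntegrityError(
                f"{self.id}: span [{self.start}, {self.end}) out of bounds "
                f"for text of length {len(text)}"
            )
        if text[self.start : self.end] != self.surface:
            raise AnnotationIntegrityError(
                f"{self.id}: surface {self.surface!r} does not match text "
                f"substring {text[self.start:self.end]!r}"
            )

    def key(self) -> tuple[str, int, int]:
        """Identity for matching/voting: (label, start, end)."""
        return (self.label.value, self.start, self.end)

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class RelationMention:
    """A directed link from an event trigger mention to a role mention."""

    id: str
    label: RelationLabel
    trigger: EntityMention
    argument: EntityMention

    def validate(self) -> None:
        if not is_trigger(self.trigger.label):
            raise AnnotationIntegrityError(
                f"{self.id}: trigger slot holds non-trigger label "
                f"{self.trigger.label.value}"
            )
        if is_trigger(self.argument.label):
            raise AnnotationIntegrityError(
                f"{self.id}: argument slot holds trigger label "
                f"{self.argument.label.value}"
            )
        allowed = ARG1_ROLES if self.label is RelationLabel.ARG1 else ARGM_ROLES
        if self.argument.label not in allowed:
            raise AnnotationIntegrityError(
                f"{self.id}: {self.label.value} cannot take argument type "
                f"{self.argument.label.value}"
            )

    def key(self) -> tuple:
        return (self.label.value, self.trigger.key(), self.argument.key())


@dataclass
class Document:
    """One patent snippet with its sentences, tokens and annotations."""

    doc_id: str
    text: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tokens: list[Token] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)
    relations: list[RelationMention] = field(default_factory=list)

    def entity_by_id(self, entity_id: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == entity_id:
                return ent
        raise KeyError(entity_id)

    def sentence_index_of(self, entity: EntityMention) -> int | None:
        """Index of the sentence containing the mention, or None."""
        for i, (s, e) in enumerate(self.sentences):
            if s <= entity.start and entity.end <= e:
                return i
        return None

    def entities_in_span(self, start: int, end: int) -> list[EntityMention]:
        return sorted(
            (m for m in self.entities if start <= m.start and m.end <= end),
            key=lambda m: (m.start, m.end),
        )

    def tokens_in_span(self, start: int, end: int) -> list[Token]:
        return [t for t in self.tokens if start <= t.start and t.end <= end]

    def validate(self) -> None:
        prev_end = -1
        for s, e in self.sentences:
            if not (0 <= s < e <= len(self.text)):
                raise AnnotationIntegrityError(
                    f"{self.doc_id}: sentence span ({s}, {e}) out of bounds"
                )
            if s < prev_end:
                raise AnnotationIntegrityError(
                    f"{self.doc_id}: sentence spans overlap or are unsorted"
                )
            prev_end = e
        for ent in self.entities:
            ent.validate(self.text)
        ids = {ent.id for ent in self.entities}
        for rel in self.relations:
            if rel.trigger.id not in ids or rel.argument.id not in ids:
                raise AnnotationIntegrityError(
                    f"{self.doc_id}: relation {rel.id} endpoint not in document"
                )
            rel.validate()


def read_document(text: str, ann: str, doc_id: str = "doc") -> Document:
    """Parse standoff annotation lines against ``text`` into a Document.

    Raises :class:`StandoffParseError` (naming the offending line number) on
    malformed lines and :class:`AnnotationIntegrityError` when offsets fall out
    of bounds, the quoted surface disagrees with the text, or a relation is
    schema-invalid.
    """
    entities: dict[str, EntityMention] = {}
    relation_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(ann.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0].strip()
        if tag.startswith("T"):
            if len(fields) != 3:
                raise StandoffParseError(
                    f"line {lineno}: entity line needs 3 tab-separated fields"
                )
            _, middle, surface = fields
            if ";" in middle:
                raise StandoffParseError(
                    f"line {lineno}: discontinuous spans are not supported"
                )
            parts = middle.split()
            if len(parts) != 3:
                raise StandoffParseError(
                    f"line {lineno}: expected 'LABEL start end', got {middle!r}"
                )
            try:
                label = parse_entity_label(parts[0])
            except StandoffParseError as exc:
                raise StandoffParseError(f"line {lineno}: {exc}") from None
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise StandoffParseError(
                    f"line {lineno}: non-integer offsets in {middle!r}"
                ) from None
            mention = EntityMention(tag, label, start, end, surface)
            mention.validate(text)
            if tag in entities:
                raise StandoffParseError(f"line {lineno}: duplicate id {tag}")
            entities[tag] = mention
        elif tag.startswith("R"):
            relation_lines.append((lineno, line))
        else:
            raise StandoffParseError(
                f"line {lineno}: unrecognized record {line!r}"
            )

    relations: list[RelationMention] = []
    for lineno, line in relation_lines:
        fields = line.split("\t")
        if len(fields) < 2:
            raise StandoffParseError(
                f"line {lineno}: relation line needs 2 tab-separated fields"
            )
        parts = fields[1].split()
        if len(parts) != 3:
            raise StandoffParseError(
                f"line {lineno}: expected 'LABEL Arg1:Ti Arg2:Tj', "
                f"got {fields[1]!r}"
            )
        try:
            rel_label = RelationLabel(parts[0])
        except ValueError:
            raise StandoffParseError(
                f"line {lineno}: unknown relation label {parts[0]!r}"
            ) from None
        slots = {}
        for part in parts[1:]:
            slot, _, ref = part.partition(":")
            if slot not in ("Arg1", "Arg2") or not ref:
                raise StandoffParseError(
                    f"line {lineno}: malformed relation slot {part!r}"
                )
            slots[slot] = ref
        if set(slots) != {"Arg1", "Arg2"}:
            raise StandoffParseError(
                f"line {lineno}: relation needs both Arg1 and Arg2 slots"
            )
        missing = [ref for ref in slots.values() if ref not in entities]
        if missing:
            raise AnnotationIntegrityError(
                f"line {lineno}: relation references unknown entity "
                f"{missing[0]!r}"
            )
        rel = RelationMention(
            fields[0].strip(), rel_label, entities[slots["Arg1"]],
            entities[slots["Arg2"]],
        )
        rel.validate()
        relations.append(rel)

    return Document(
        doc_id=doc_id,
        text=text,
        entities=sorted(entities.values(), key=lambda m: (m.start, m.end, m.id)),
        relations=relations,
    )


def write_annotations(doc: Document) -> str:
    """Serialize a document's entities and relations as standoff lines.

    Round-trip guarantee: ``read_document(doc.text, write_annotations(doc))``
    reproduces the same entity and relation sets.
    """
    doc.validate()
    lines = []
    for ent in doc.entities:
        lines.append(
            f"{ent.id}\t{ent.label.value} {ent.start} {ent.end}\t{ent.surface}"
        )
    for rel in doc.relations:
        lines.append(
            f"{rel.id}\t{rel.label.value} Arg1:{rel.trigger.id} "
            f"Arg2:{rel.argument.id}"
        )
    return "".join(line + "\n" for line in lines)


def read_document_pair(txt_path: str | Path) -> Document:
    """Read a ``<id>.txt`` / ``<id>.ann`` pair; a missing .ann means empty."""
    txt_path = Path(txt_path)
    ann_path = txt_path.with_suffix(".ann")
    text = txt_path.read_text(encoding="utf-8")
    ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
    return read_document(text, ann, doc_id=txt_path.stem)


def write_document_pair(doc: Document, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    (directory / f"{doc.doc_id}.ann").write_text(
        write_annotations(doc), encoding="utf-8"
    )


def read_corpus_dir(directory: str | Path) -> list[Document]:
    directory = Path(directory)
    return [read_document_pair(p) for p in sorted(directory.glob("*.txt"))]


def write_corpus_dir(docs: Iterable[Document], directory: str | Path) -> None:
    for doc in docs:
        write_document_pair(doc, directory)
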