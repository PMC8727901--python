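"""Trigger-role relation extraction via entity-type masking.

Candidate pairs are the Cartesian product of event triggers and semantic roles
within each sentence (EXAMPLE_LABEL mentions never take part in relations).
Each candidate is represented by the sentence's token sequence with *every*
entity mention collapsed to a single token equal to its label name; a binary
classifier decides whether the pair is related, and the ARG1/ARGM label is
then assigned deterministically from the argument's role type (compound roles
are ARG1; time/temperature/yield roles are ARGM).

The classifier backend is pluggable; the default is a regularized logistic
regression (scikit-learn) over bag-of-masked-tokens, between-pair tokens,
trigger surface, argument label and token-distance features, with weights
exported to a plain JSON file for reproducible serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .preprocess import ConfigurationError
from .standoff import (
    ARGM_ROLES,
    ContractError,
    Document,
    EntityLabel,
    EntityMention,
    RelationLabel,
    RelationMention,
    is_trigger,
)

CLASSIFIER_FORMAT = "chemrext-relation-v1"


def assign_relation_label(
    trigger_label: EntityLabel, argument_label: EntityLabel
) -> RelationLabel:
    """ARGM for auxiliary roles (time, temperature, yields); ARG1 otherwise."""
    if not is_trigger(trigger_label):
        raise ContractError(f"{trigger_label.value} is not a trigger type")
    if is_trigger(argument_label):
        raise ContractError(f"{argument_label.value} is not a role type")
    if argument_label is EntityLabel.EXAMPLE_LABEL:
        raise ContractError("EXAMPLE_LABEL never takes part in relations")
    return (
        RelationLabel.ARGM if argument_label in ARGM_ROLES else RelationLabel.ARG1
    )


@dataclass
class CandidatePair:
    """A same-sentence trigger-role pair with its masked token sequence.

    ``trigger_index``/``argument_index`` locate the two masked label tokens in
    ``masked_tokens``.
    """

    doc_id: str
    sentence_index: int
    trigger: EntityMention
    argument: EntityMention
    masked_tokens: list[str]
    trigger_index: int
    argument_index: int


def _mask_sentence(
    doc: Document, sentence_index: int
) -> tuple[list[str], dict[str, int]]:
    """Sentence tokens with every entity run collapsed to its label name.

    Returns the masked token list and a map entity id -> masked position.
    """
    s, e = doc.sentences[sentence_index]
    tokens = doc.tokens_in_span(s, e)
    entities = doc.entities_in_span(s, e)
    masked: list[str] = []
    positions: dict[str, int] = {}
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        hit = next(
            (m for m in entities if m.start <= tok.start and tok.end <= m.end),
            None,
        )
        if hit is None:
            masked.append(tok.surface)
            i += 1
            continue
        positions[hit.id] = len(masked)
        masked.append(hit.label.value)
        while i < len(tokens) and tokens[i].end <= hit.end:
            i += 1
    return masked, positions


def generate_candidates(doc: Document) -> list[CandidatePair]:
    """All same-sentence trigger x role pairs (EXAMPLE_LABEL excluded)."""
    pairs: list[CandidatePair] = []
    for si, (s, e) in enumerate(doc.sentences):
        entities = doc.entities_in_span(s, e)
        triggers = [m for m in entities if is_trigger(m.label)]
        roles = [
            m
            for m in entities
            if not is_trigger(m.label) and m.label is not EntityLabel.EXAMPLE_LABEL
        ]
        if not triggers or not roles:
            continue
        masked, positions = _mask_sentence(doc, si)
        for trig in triggers:
            for role in roles:
                pairs.append(
                    CandidatePair(
                        doc_id=doc.doc_id,
                        sentence_index=si,
                        trigger=trig,
                        argument=role,
                        masked_tokens=list(masked),
                        trigger_index=positions[trig.id],
                        argument_index=positions[role.id],
                    )
                )
    return pairs


def mask_pair(doc: Document, pair: CandidatePair) -> list[str]:
    """Masked token sequence for a candidate pair belonging to ``doc``."""
    if pair.doc_id != doc.doc_id or pair.sentence_index >= len(doc.sentences):
        raise ContractError("candidate pair does not belong to this document")
    ids = {m.id for m in doc.entities}
    if pair.trigger.id not in ids or pair.argument.id not in ids:
        raise ContractError("candidate pair mentions are not in the document")
    masked, _ = _mask_sentence(doc, pair.sentence_index)
    return masked


def pair_features(pair: CandidatePair) -> dict[str, float]:
    feats: dict[str, float] = {}
    for tok in pair.masked_tokens:
        feats[f"tok={tok}"] = 1.0
    lo, hi = sorted((pair.trigger_index, pair.argument_index))
    for tok in pair.masked_tokens[lo + 1 : hi]:
        feats[f"between={tok}"] = 1.0
    feats[f"trig={pair.trigger.surface.lower()}"] = 1.0
    feats[f"triglab={pair.trigger.label.value}"] = 1.0
    feats[f"arglab={pair.argument.label.value}"] = 1.0
    dist = hi - lo
    feats["dist"] = float(dist)
    feats[f"distb={min(dist, 10)}"] = 1.0
    feats["trig_first" if pair.trigger_index < pair.argument_index
          else "arg_first"] = 1.0
    return feats


@dataclass
class ClassifierConfig:
    seed: int = 0
    threshold: float = 0.5
    C: float = 10.0


@dataclass
class RelationClassifier:
    """Binary relation decision: accept a candidate iff score >= threshold."""

    backend_name: str
    parameters: dict
    threshold: float
    seed: int
    _weights: dict | None = field(default=None, repr=False, compare=False)

    def score(self, pair: CandidatePair) -> float:
        if self._weights is None:
            self._weights = self.parameters["features"]
        z = self.parameters["intercept"]
        w = self._weights
        for f, v in pair_features(pair).items():
            z += w.get(f, 0.0) * v
        return 1.0 / (1.0 + math.exp(-z))

    def save(self, path: str | Path) -> None:
        payload = {
            "format": CLASSIFIER_FORMAT,
            "backend": self.backend_name,
            "threshold": self.threshold,
            "seed": self.seed,
            "parameters": self.parameters,
        }
        Path(path).write_text(
            json.dumps(payload, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "RelationClassifier":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != CLASSIFIER_FORMAT:
            raise ConfigurationError(f"unrecognized classifier file {path}")
        return cls(
            backend_name=payload["backend"],
            parameters=payload["parameters"],
            threshold=payload["threshold"],
            seed=payload["seed"],
        )


def gold_candidate_labels(doc: Document) -> list[tuple[CandidatePair, bool]]:
    """Label each candidate by whether it matches an annotated relation."""
    gold = {
        (rel.trigger.key(), rel.argument.key()) for rel in doc.relations
    }
    return [
        (pair, (pair.trigger.key(), pair.argument.key()) in gold)
        for pair in generate_candidates(doc)
    ]


def train_classifier(
    pairs: Sequence[tuple[CandidatePair, bool]],
    config: ClassifierConfig | None = None,
) -> RelationClassifier:
    """Fit the default logistic-regression backend on labeled candidates."""
    config = config or ClassifierConfig()
    labels = [bool(y) for _, y in pairs]
    if len(set(labels)) < 2:
        raise ConfigurationError(
            "training needs at least one positive and one negative candidate"
        )
    X_dicts = [pair_features(p) for p, _ in pairs]
    vec = DictVectorizer(sparse=True)
    X = vec.fit_transform(X_dicts).tocsr()
    # liblinear accepts only 32-bit sparse indices
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    clf = LogisticRegression(
        C=config.C,
        solver="liblinear",
        random_state=config.seed,
        max_iter=2000,
    )
    clf.fit(X, labels)
    weights = {
        name: round(float(w), 12)
        for name, w in zip(vec.get_feature_names_out(), clf.coef_[0])
        if w != 0.0
    }
    parameters = {
        "features": weights,
        "intercept": round(float(clf.intercept_[0]), 12),
    }
    return RelationClassifier(
        backend_name="logreg",
        parameters=parameters,
        threshold=config.threshold,
        seed=config.seed,
    )


def predict_relations(
    model: RelationClassifier, doc: Document
) -> list[RelationMention]:
    """Score all candidates and materialize accepted ones as relations."""
    relations: list[RelationMention] = []
    for pair in generate_candidates(doc):
        if model.score(pair) >= model.threshold:
            label = assign_relation_label(pair.trigger.label, pair.argument.label)
            relations.append(
                RelationMention(
                    f"R{len(relations) + 1}", label, pair.trigger, pair.argument
                )
            )
    return relations
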