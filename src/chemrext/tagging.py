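"""BIO sequence labeling over punctuation-level tokens.

One joint tagger covers the 10 semantic roles and the 2 event triggers (25 BIO
states).  The tagger backend is a pluggable contract; the default backend is a
linear-chain averaged structured perceptron over surface features (token
string, lowercase, character shape, 2-4 character prefixes/suffixes,
punctuation flag, a +/-2 token window) with learned tag-transition scores and
Viterbi decoding.  Training is deterministic under a seed, and a model
serializes to one versioned JSON file byte-for-byte reproducibly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import ConfigurationError, Token
from .standoff import ContractError, Document, EntityLabel, EntityMention

MODEL_FORMAT = "chemrext-tagger-v1"


class AlignmentError(ValueError):
    """A gold entity span does not coincide with token boundaries."""


@dataclass(frozen=True)
class BioTag:
    """A BIO tag: prefix B/I/O plus the entity label (absent for O)."""

    prefix: str
    label: EntityLabel | None = None

    def __post_init__(self) -> None:
        if self.prefix not in ("B", "I", "O"):
            raise ValueError(f"invalid BIO prefix {self.prefix!r}")
        if (self.label is None) != (self.prefix == "O"):
            raise ValueError("label must be absent exactly when prefix is O")

    def __str__(self) -> str:
        return "O" if self.prefix == "O" else f"{self.prefix}-{self.label.value}"

    @classmethod
    def from_string(cls, s: str) -> "BioTag":
        if s == "O":
            return cls("O")
        prefix, _, label = s.partition("-")
        return cls(prefix, EntityLabel(label))


#: Deterministic full BIO state inventory (O first, then B/I per label).
FULL_LABEL_SET: list[str] = ["O"] + [
    f"{p}-{lab.value}" for lab in EntityLabel for p in ("B", "I")
]

OUTSIDE = BioTag("O")


def snap_to_token_boundaries(
    entity: EntityMention, tokens: Sequence[Token], text: str
) -> EntityMention:
    """Widen an entity outward to the nearest enclosing token boundaries."""
    starts = sorted(t.start for t in tokens)
    ends = sorted(t.end for t in tokens)
    new_start = max((s for s in starts if s <= entity.start), default=entity.start)
    new_end = min((e for e in ends if e >= entity.end), default=entity.end)
    return EntityMention(
        entity.id, entity.label, new_start, new_end, text[new_start:new_end]
    )


def encode_bio(
    tokens: Sequence[Token], entities: Sequence[EntityMention]
) -> list[BioTag]:
    """One BIO tag per token; entities must align to token boundaries."""
    tags = [OUTSIDE] * len(tokens)
    start_index = {t.start: i for i, t in enumerate(tokens)}
    end_index = {t.end: i for i, t in enumerate(tokens)}
    ordered = sorted(entities, key=lambda m: (m.start, m.end))
    prev_end = -1
    for ent in ordered:
        if ent.start < prev_end:
            raise AlignmentError(f"entity {ent.id} overlaps a previous entity")
        prev_end = ent.end
        if ent.start not in start_index or ent.end not in end_index:
            raise AlignmentError(
                f"entity {ent.id} [{ent.start}, {ent.end}) {ent.surface!r} "
                f"is not aligned to token boundaries"
            )
        i0, i1 = start_index[ent.start], end_index[ent.end]
        if i1 < i0:
            raise AlignmentError(f"entity {ent.id} spans no complete token")
        tags[i0] = BioTag("B", ent.label)
        for i in range(i0 + 1, i1 + 1):
            tags[i] = BioTag("I", ent.label)
    return tags


def decode_bio(
    tokens: Sequence[Token],
    tags: Sequence[BioTag | str],
    text: str | None = None,
) -> list[EntityMention]:
    """Turn a tag sequence back into entity mentions (lenient decoding).

    An ``I-`` tag following ``O`` or carrying a different label than its
    predecessor is repaired as ``B-``.  Surfaces come from ``text`` when given,
    otherwise they are reconstructed from token surfaces with offset gaps
    filled by spaces.
    """
    if len(tags) != len(tokens):
        raise ContractError(
            f"{len(tags)} tags for {len(tokens)} tokens"
        )
    parsed = [t if isinstance(t, BioTag) else BioTag.from_string(t) for t in tags]
    entities: list[EntityMention] = []
    run_start: int | None = None
    run_label: EntityLabel | None = None

    def close(last_index: int) -> None:
        nonlocal run_start, run_label
        if run_start is None:
            return
        start = tokens[run_start].start
        end = tokens[last_index].end
        if text is not None:
            surface = text[start:end]
        else:
            pieces = []
            pos = start
            for t in tokens[run_start : last_index + 1]:
                pieces.append(" " * (t.start - pos))
                pieces.append(t.surface)
                pos = t.end
            surface = "".join(pieces)
        entities.append(
            EntityMention(f"T{len(entities) + 1}", run_label, start, end, surface)
        )
        run_start = run_label = None

    for i, tag in enumerate(parsed):
        if tag.prefix == "O":
            close(i - 1)
        elif tag.prefix == "B" or run_label != tag.label:
            close(i - 1)
            run_start, run_label = i, tag.label
    close(len(parsed) - 1)
    return entities


# ---------------------------------------------------------------------------
# Surface features


def _shape(s: str) -> str:
    out = []
    prev = ""
    for ch in s:
        cls = "d" if ch.isdigit() else ("A" if ch.isupper() else
                                        ("a" if ch.isalpha() else "p"))
        if cls != prev:
            out.append(cls)
            prev = cls
    return "".join(out)


def token_features(tokens: Sequence[Token], i: int) -> list[str]:
    t = tokens[i].surface
    low = t.lower()
    feats = [
        f"w0={t}",
        f"l0={low}",
        f"sh0={_shape(t)}",
    ]
    if len(t) == 1 and not t.isalnum():
        feats.append("punct0")
    for k in (2, 3, 4):
        if len(low) >= k:
            feats.append(f"pre{k}={low[:k]}")
            feats.append(f"suf{k}={low[-k:]}")
    for off in (-2, -1, 1, 2):
        j = i + off
        if 0 <= j < len(tokens):
            nb = tokens[j].surface
            feats.append(f"l{off}={nb.lower()}")
            feats.append(f"sh{off}={_shape(nb)}")
        else:
            feats.append(f"bnd{off}")
    left = tokens[i - 1].surface.lower() if i > 0 else "<s>"
    right = tokens[i + 1].surface.lower() if i + 1 < len(tokens) else "</s>"
    feats.append(f"lg={left}|{low}")
    feats.append(f"rg={low}|{right}")
    return feats


# ---------------------------------------------------------------------------
# Default backend: linear-chain averaged structured perceptron


class StructuredPerceptronTagger:
    """Linear-chain sequence tagger trained with the averaged perceptron.

    Emission scores are sums of per-feature weight vectors; transition scores
    are a dense (L+1) x L matrix whose extra row is the sentence-start state.
    Decoding is exact Viterbi.  Averaging uses the standard accumulator trick,
    so training cost stays proportional to the number of mistakes.
    """

    backend_name = "perceptron"

    def __init__(self, labels: Sequence[str], epochs: int = 8, seed: int = 0):
        self.labels = list(labels)
        self.n_labels = len(self.labels)
        self.epochs = epochs
        self.seed = seed
        self.weights: dict[str, np.ndarray] = {}
        self.trans = np.zeros((self.n_labels + 1, self.n_labels))
        self._acc: dict[str, np.ndarray] = {}
        self._trans_acc = np.zeros_like(self.trans)
        self._steps = 0

    # -- scoring -----------------------------------------------------------

    def _emissions(self, feats: Sequence[Sequence[str]]) -> np.ndarray:
        E = np.zeros((len(feats), self.n_labels))
        get = self.weights.get
        for i, row in enumerate(feats):
            acc = E[i]
            for f in row:
                w = get(f)
                if w is not None:
                    acc += w
        return E

    def _viterbi(self, E: np.ndarray) -> list[int]:
        n = E.shape[0]
        if n == 0:
            return []
        back = np.zeros((n, self.n_labels), dtype=np.int64)
        score = self.trans[self.n_labels] + E[0]
        for i in range(1, n):
            cand = score[:, None] + self.trans[: self.n_labels]
            back[i] = np.argmax(cand, axis=0)
            score = cand[back[i], np.arange(self.n_labels)] + E[i]
        path = [int(np.argmax(score))]
        for i in range(n - 1, 0, -1):
            path.append(int(back[i, path[-1]]))
        return path[::-1]

    # -- training ----------------------------------------------------------

    def _bump(self, feature: str, label_index: int, delta: float) -> None:
        w = self.weights.get(feature)
        if w is None:
            w = self.weights[feature] = np.zeros(self.n_labels)
            self._acc[feature] = np.zeros(self.n_labels)
        w[label_index] += delta
        self._acc[feature][label_index] += self._steps * delta

    def fit(self, sentences: Sequence[tuple[list[list[str]], list[int]]]) -> None:
        """Train on (feature rows, gold state indices) pairs."""
        rng = np.random.default_rng(self.seed)
        order = np.arange(len(sentences))
        for _ in range(self.epochs):
            rng.shuffle(order)
            for si in order:
                feats, gold = sentences[si]
                self._steps += 1
                pred = self._viterbi(self._emissions(feats))
                if pred == gold:
                    continue
                for i, (g, p) in enumerate(zip(gold, pred)):
                    if g != p:
                        for f in feats[i]:
                            self._bump(f, g, 1.0)
                            self._bump(f, p, -1.0)
                prev_g = prev_p = self.n_labels
                for g, p in zip(gold, pred):
                    if (prev_g, g) != (prev_p, p):
                        self.trans[prev_g, g] += 1.0
                        self.trans[prev_p, p] -= 1.0
                        self._trans_acc[prev_g, g] += self._steps
                        self._trans_acc[prev_p, p] -= self._steps
                    prev_g, prev_p = g, p
        self._average()

    def _average(self) -> None:
        if self._steps == 0:
            return
        t = float(self._steps + 1)
        for f, w in self.weights.items():
            w -= self._acc[f] / t
        self.trans -= self._trans_acc / t
        self._acc = {}
        self._trans_acc = np.zeros_like(self.trans)

    # -- prediction --------------------------------------------------------

    def predict(self, feats: Sequence[Sequence[str]]) -> list[str]:
        return [self.labels[i] for i in self._viterbi(self._emissions(feats))]

    # -- serialization -----------------------------------------------------

    def to_parameters(self) -> dict:
        return {
            "weights": {f: [round(v, 10) for v in w] for f, w in
                        sorted(self.weights.items())},
            "transitions": [[round(v, 10) for v in row] for row in self.trans],
            "epochs": self.epochs,
        }

    @classmethod
    def from_parameters(
        cls, params: dict, labels: Sequence[str], seed: int
    ) -> "StructuredPerceptronTagger":
        obj = cls(labels, epochs=params.get("epochs", 8), seed=seed)
        obj.weights = {
            f: np.asarray(w, dtype=float) for f, w in params["weights"].items()
        }
        obj.trans = np.asarray(params["transitions"], dtype=float)
        return obj


_TAGGER_BACKENDS = {"perceptron": StructuredPerceptronTagger}


def register_tagger_backend(name: str, cls) -> None:
    """Plug in an alternative tagger backend (e.g. a transformer wrapper)."""
    _TAGGER_BACKENDS[name] = cls


@dataclass
class TaggerConfig:
    backend: str = "perceptron"
    seed: int = 0
    epochs: int = 8
    #: widen misaligned gold spans to token boundaries instead of failing
    snap_spans: bool = False


@dataclass
class TaggerModel:
    """A trained tagger: backend name, opaque parameters, state inventory."""

    backend_name: str
    parameters: dict
    label_set: list[str]
    seed: int
    _backend: object = field(default=None, repr=False, compare=False)

    def backend(self):
        if self._backend is None:
            cls = _TAGGER_BACKENDS[self.backend_name]
            self._backend = cls.from_parameters(
                self.parameters, self.label_set, self.seed
            )
        return self._backend

    def save(self, path: str | Path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "backend": self.backend_name,
            "label_set": self.label_set,
            "seed": self.seed,
            "parameters": self.parameters,
        }
        Path(path).write_text(
            json.dumps(payload, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != MODEL_FORMAT:
            raise ConfigurationError(f"unrecognized model file {path}")
        return cls(
            backend_name=payload["backend"],
            parameters=payload["parameters"],
            label_set=payload["label_set"],
            seed=payload["seed"],
        )


def _sentence_training_data(
    doc: Document, label_index: dict[str, int], snap: bool
) -> list[tuple[list[list[str]], list[int]]]:
    out = []
    for s, e in doc.sentences:
        tokens = doc.tokens_in_span(s, e)
        if not tokens:
            continue
        entities = doc.entities_in_span(s, e)
        if snap:
            entities = [
                snap_to_token_boundaries(m, tokens, doc.text) for m in entities
            ]
        tags = encode_bio(tokens, entities)
        feats = [token_features(tokens, i) for i in range(len(tokens))]
        out.append((feats, [label_index[str(t)] for t in tags]))
    return out


def train_tagger(corpus: Sequence[Document], config: TaggerConfig | None = None
                 ) -> TaggerModel:
    """Train the joint role+trigger tagger on pre-tokenized gold documents."""
    if not corpus:
        raise ConfigurationError("cannot train a tagger on an empty corpus")
    config = config or TaggerConfig()
    label_set = list(FULL_LABEL_SET)
    label_index = {lab: i for i, lab in enumerate(label_set)}
    sentences = []
    for doc in corpus:
        if not doc.tokens:
            raise ContractError(f"document {doc.doc_id} is not tokenized")
        sentences.extend(_sentence_training_data(doc, label_index,
                                                 config.snap_spans))
    backend_cls = _TAGGER_BACKENDS[config.backend]
    backend = backend_cls(label_set, epochs=config.epochs, seed=config.seed)
    backend.fit(sentences)
    return TaggerModel(
        backend_name=config.backend,
        parameters=backend.to_parameters(),
        label_set=label_set,
        seed=config.seed,
        _backend=backend,
    )


def predict_entities(model: TaggerModel, doc: Document) -> list[EntityMention]:
    """Tag each sentence and decode BIO runs into entity mentions."""
    if not doc.tokens:
        if doc.text.strip():
            raise ContractError(f"document {doc.doc_id} is not tokenized")
        return []
    backend = model.backend()
    entities: list[EntityMention] = []
    for s, e in doc.sentences:
        tokens = doc.tokens_in_span(s, e)
        if not tokens:
            continue
        feats = [token_features(tokens, i) for i in range(len(tokens))]
        tags = backend.predict(feats)
        entities.extend(decode_bio(tokens, tags, doc.text))
    entities.sort(key=lambda m: (m.start, m.end))
    for i, ent in enumerate(entities, start=1):
        ent.id = f"T{i}"
    return entities


def ensemble_vote(
    predictions: Sequence[Sequence[EntityMention]], k: int
) -> list[EntityMention]:
    """Majority voting over k prediction sets.

    An entity (identified by label+span) survives iff it appears in strictly
    more than k/2 sets.  Overlapping survivors are resolved by keeping the
    higher-vote entity; ties go to the earlier start, then the longer span.
    """
    if k != len(predictions):
        raise ContractError(
            f"k={k} does not match {len(predictions)} prediction sets"
        )
    votes: Counter[tuple] = Counter()
    representative: dict[tuple, EntityMention] = {}
    for pred_set in predictions:
        seen = set()
        for ent in pred_set:
            key = ent.key()
            if key in seen:
                continue
            seen.add(key)
            votes[key] += 1
            representative.setdefault(key, ent)
    survivors = [key for key, c in votes.items() if 2 * c > k]
    survivors.sort(
        key=lambda key: (-votes[key], key[1], -(key[2] - key[1]), key[0])
    )
    selected: list[EntityMention] = []
    for key in survivors:
        ent = representative[key]
        if not any(ent.overlaps(other) for other in selected):
            selected.append(ent)
    selected.sort(key=lambda m: (m.start, m.end))
    return [
        EntityMention(f"T{i}", m.label, m.start, m.end, m.surface)
        for i, m in enumerate(selected, start=1)
    ]
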