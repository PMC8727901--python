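"""Sentence segmentation and two-stage tokenization for chemical patent text.

Chemical names and numeric expressions ("7-Bromo-4-(pyridin-2-yl)...", "6.5 mg",
"2%") defeat general-purpose tokenizers, which split them inconsistently.  The
first stage here treats *every* punctuation character as a token separator, so a
long chemical name decomposes into a fully predictable alternation of
alphanumeric runs and single punctuation marks.  The second stage decomposes
each token into word pieces from a vocabulary (greedy longest-prefix-first,
continuation pieces marked with a leading ``##``), so downstream models that
operate on a closed vocabulary can consume the output.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence


class ConfigurationError(ValueError):
    """Raised when an operation is invoked with an unusable configuration."""


#: Abbreviations whose trailing period must not end a sentence.  "sat." and
#: "aq." are the load-bearing entries: splitting "sat. aq. NH4Cl" detaches the
#: chemical from its clause and loses the trigger-chemical relation.
DEFAULT_ABBREVIATIONS = frozenset(
    {"sat.", "aq.", "approx.", "conc.", "vs.", "e.g.", "i.e.", "no.", "fig."}
)

#: Marker emitted when a token cannot be decomposed into vocabulary pieces.
UNKNOWN_MARKER = "[UNK]"

#: Prefix carried by continuation word pieces.
CONTINUATION = "##"

# Alphanumeric runs (underscore counts as punctuation) or a single
# non-whitespace character.  Alternation order makes the run win on
# alphanumerics, leaving every punctuation code point as its own match.
_TOKEN_RE = re.compile(r"[^\W_]+|\S", re.UNICODE)

_TERMINATORS = ".!?"


@dataclass
class Token:
    """A surface token anchored to half-open character offsets.

    ``subwords`` is ``None`` until the second tokenization stage runs; after
    alignment it holds vocabulary pieces (continuation pieces prefixed with
    ``##``) or the single unknown marker.
    """

    surface: str
    start: int
    end: int
    subwords: list[str] | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.surface):
            raise ValueError(
                f"token span [{self.start}, {self.end}) does not cover "
                f"surface {self.surface!r}"
            )


def _ends_with_abbreviation(text: str, dot: int, abbreviations: frozenset[str]) -> bool:
    """True when the period at ``dot`` terminates a guarded abbreviation."""
    j = dot
    while j > 0 and not text[j - 1].isspace():
        j -= 1
    tail = text[j : dot + 1].lower()
    for abbr in abbreviations:
        if tail == abbr:
            return True
        if tail.endswith(abbr) and not tail[-len(abbr) - 1].isalnum():
            # e.g. "(sat." — the abbreviation sits after an opening bracket
            return True
    return False


def segment_sentences(
    text: str, abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (0-based, half-open, whitespace-trimmed).

    Terminators are ``.``, ``!``, ``?`` followed by whitespace or end of text,
    plus the newline character (patent headings sit on their own lines).  A
    period is suppressed as a terminator when the token it ends is a guarded
    abbreviation, so "washed with sat. aq. NH4Cl" stays in one sentence.
    """
    guard = frozenset(a.lower() for a in abbreviations)
    spans: list[tuple[int, int]] = []
    n = len(text)

    def flush(s: int, e: int) -> None:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            spans.append((s, e))

    sent_start = 0
    for i, ch in enumerate(text):
        if ch == "\n":
            flush(sent_start, i)
            sent_start = i + 1
        elif ch in _TERMINATORS:
            follower = text[i + 1] if i + 1 < n else ""
            if follower and not follower.isspace():
                continue  # "48.1", "6.5" — terminator glued to the next char
            if ch == "." and _ends_with_abbreviation(text, i, guard):
                continue
            flush(sent_start, i + 1)
            sent_start = i + 1
    flush(sent_start, n)
    return spans


def tokenize_punct(text: str, offset: int = 0) -> list[Token]:
    """First-stage tokenization: every punctuation character separates tokens.

    Maximal alphanumeric runs become tokens, every other non-whitespace code
    point (hyphens, brackets, commas, decimal points, ``%``, ``°``, ``_``)
    becomes a single-character token, and whitespace is consumed.  ``offset``
    shifts the emitted spans so they index into the enclosing document.
    """
    return [
        Token(m.group(0), m.start() + offset, m.end() + offset)
        for m in _TOKEN_RE.finditer(text)
    ]


@dataclass
class SubwordVocabulary:
    """Word-piece inventory for the second tokenization stage.

    ``entries`` holds initial pieces (no prefix) and continuation pieces
    (prefixed ``##``); the unknown marker is never a member.
    """

    entries: frozenset[str] = field(default_factory=frozenset)
    unknown_marker: str = UNKNOWN_MARKER

    def __post_init__(self) -> None:
        self.entries = frozenset(self.entries)
        if self.unknown_marker in self.entries:
            raise ConfigurationError("unknown marker must not be a vocabulary entry")

    def save(self, path: str | Path) -> None:
        lines = [self.unknown_marker] + sorted(self.entries)
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SubwordVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ConfigurationError(f"empty vocabulary file: {path}")
        return cls(entries=frozenset(lines[1:]), unknown_marker=lines[0])


def subword_align(token: Token, vocab: SubwordVocabulary) -> Token:
    """Decompose a token into vocabulary pieces, greedy longest-prefix-first.

    Repeatedly take the longest entry matching the remaining suffix (pieces
    after the first must carry the ``##`` continuation prefix).  If any step
    finds no match the whole token maps to ``[vocab.unknown_marker]``.
    """
    s = token.surface
    pieces: list[str] = []
    pos = 0
    while pos < len(s):
        marker = CONTINUATION if pos else ""
        found = None
        for length in range(len(s) - pos, 0, -1):
            candidate = marker + s[pos : pos + length]
            if candidate in vocab.entries:
                found = candidate
                pos += length
                break
        if found is None:
            return replace(token, subwords=[vocab.unknown_marker])
        pieces.append(found)
    return replace(token, subwords=pieces)


def build_vocabulary(
    corpus: Sequence, max_size: int = 2000, max_piece_len: int = 6
) -> SubwordVocabulary:
    """Frequency-ranked character n-gram vocabulary over a document corpus.

    Every single character observed in the corpus is included in both initial
    and continuation form, which guarantees that :func:`subword_align` never
    yields the unknown marker on in-corpus text.  Remaining capacity up to
    ``max_size`` is filled with the most frequent longer pieces (ties broken
    lexicographically, so the result is deterministic).
    """
    if not corpus:
        raise ConfigurationError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    chars: set[str] = set()
    for doc in corpus:
        tokens = getattr(doc, "tokens", None)
        if not tokens:
            text = getattr(doc, "text", None)
            if text is None:
                text = str(doc)
            tokens = tokenize_punct(text)
        for tok in tokens:
            s = tok.surface
            chars.update(s)
            for i in range(len(s)):
                marker = CONTINUATION if i else ""
                for length in range(2, min(max_piece_len, len(s) - i) + 1):
                    counts[marker + s[i : i + length]] += 1
    if max_size < len(chars):
        raise ConfigurationError(
            f"max_size {max_size} is below the alphabet size {len(chars)}"
        )
    base = set(chars) | {CONTINUATION + c for c in chars}
    room = max(0, max_size - len(base))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    extra = [piece for piece, _ in ranked if piece not in base][:room]
    return SubwordVocabulary(entries=frozenset(base | set(extra)))


def tokenize_document(doc, vocab: SubwordVocabulary | None = None,
                      abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS):
    """Populate ``doc.sentences`` (if unset) and ``doc.tokens`` in place."""
    if not doc.sentences:
        doc.sentences = segment_sentences(doc.text, abbreviations)
    tokens: list[Token] = []
    for start, end in doc.sentences:
        tokens.extend(tokenize_punct(doc.text[start:end], offset=start))
    if vocab is not None:
        tokens = [subword_align(t, vocab) for t in tokens]
    doc.tokens = tokens
    return doc
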