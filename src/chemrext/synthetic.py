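"""Templated synthetic patent snippets with gold entities and relations.

The generator emulates the structure of reaction paragraphs in chemical
patents: an example heading, optionally a sub-step heading naming the target
compound, one to three reaction/workup sentences drawing punctuation-rich
IUPAC-like compound names, temperature/time/yield expressions, and trigger
verbs, plus the two phenomena the cross-sentence rules exist for ("sat. aq."
clauses and separate "Yield: ..." sentences).  Gold relations follow the
ARG1/ARGM schema; only yield-sentence documents carry cross-sentence gold
relations.  Generation is fully deterministic under the config seed.

The compound-name lexicons are built compositionally (locants, hyphens,
brackets, ring/suffix morphemes) so the punctuation tokenizer is exercised;
the names make no claim to chemical validity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .preprocess import tokenize_punct
from .standoff import (
    Document,
    EntityLabel,
    EntityMention,
    RelationLabel,
    RelationMention,
    write_document_pair,
)

E = EntityLabel

_PREFIXES = ["bromo", "chloro", "fluoro", "methyl", "ethyl", "hydroxy",
             "amino", "nitro", "cyano", "methoxy", "phenyl", "benzyl"]
_CORES = ["pyridin", "pyrimidin", "quinolin", "oxazol", "thiazol", "imidazol",
          "piperidin", "pyrazol", "morpholin", "naphthalen", "indol", "furan"]
_SUFFIXES = ["oxazine", "amine", "benzonitrile", "acetate", "carboxamide",
             "acetamide", "benzoate", "aniline", "phenol", "sulfonamide"]
_SOLVENTS = ["EtOAc", "THF", "DMF", "dichloromethane", "methanol", "toluene",
             "acetonitrile", "dioxane", "ethanol", "DMSO"]
_SALTS = ["NH4Cl", "NaHCO3", "NaCl", "Na2SO4", "K2CO3", "MgSO4", "LiCl"]
_REAGENTS = ["palladium acetate", "triethylamine", "sodium hydride", "DIPEA",
             "potassium carbonate", "HATU", "sodium borohydride", "TFA"]
_SETUP_VERBS = ["stirred", "heated", "refluxed", "agitated", "treated"]
_WORKUP_VERBS = ["concentrated", "filtered", "evaporated", "dried"]


@dataclass
class GeneratorConfig:
    n_documents: int = 100
    seed: int = 0
    #: fraction of documents with a sub-step heading (Figure-3-like structure)
    substep_fraction: float = 0.3
    #: fraction of documents with a "sat. aq." workup clause
    satag_fraction: float = 0.2
    #: fraction of documents describing the yield in a separate sentence
    yield_sentence_fraction: float = 0.3
    #: size of each generated compound-name lexicon
    lexicon_size: int = 30

    def validate(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be non-negative")
        for name in ("substep_fraction", "satag_fraction",
                     "yield_sentence_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")
        if self.lexicon_size < 1:
            raise ValueError("lexicon_size must be positive")


def _chem_name(rng: random.Random) -> str:
    """A punctuation-rich IUPAC-like name (locants, hyphens, brackets)."""
    l1, l2, l3 = (rng.randint(1, 9) for _ in range(3))
    pre = rng.choice(_PREFIXES)
    core = rng.choice(_CORES)
    suf = rng.choice(_SUFFIXES)
    pattern = rng.randrange(4)
    if pattern == 0:
        return f"{l1}-{pre}-{l2}-({core}-{rng.randint(1, 4)}-yl)-{suf}"
    if pattern == 1:
        return (f"{l1},{l2}-di{pre}-2H-{core}({rng.choice('ab')})"
                f"({l1},{l3}){suf}")
    if pattern == 2:
        return f"methyl {l1}-{pre}-{core}-{l2}-carboxylate"
    return f"{l1}-({pre}methyl)-{core}-{l2}({l3}H)-{suf}"


@dataclass
class _Pools:
    starting: list[str]
    reagents: list[str]
    products: list[str]
    others: list[str]
    solvents: list[str]

    @classmethod
    def build(cls, rng: random.Random, size: int) -> "_Pools":
        def pool() -> list[str]:
            names: list[str] = []
            while len(names) < size:
                name = _chem_name(rng)
                if name not in names:
                    names.append(name)
            return names

        return cls(
            starting=pool(),
            reagents=[*_REAGENTS, *pool()][:max(size, len(_REAGENTS))],
            products=pool(),
            others=[*_SALTS, *pool()][:max(size, len(_SALTS))],
            solvents=_SOLVENTS[:],
        )


class _Builder:
    """Accumulates sentences of (literal | (surface, label)) segments."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.text_parts: list[str] = []
        self.pos = 0
        self.sentences: list[tuple[int, int]] = []
        self.entities: list[EntityMention] = []
        self.relations: list[RelationMention] = []

    def sentence(self, segments: Sequence, sep: str = " ") -> dict[str, EntityMention]:
        """Append one sentence; returns a handle map for relation wiring.

        Entity segments are (surface, label) or (surface, label, handle)
        tuples; literal strings pass through unchanged.
        """
        start = self.pos
        handles: dict[str, EntityMention] = {}
        n_ent = 0
        for seg in segments:
            if isinstance(seg, str):
                self.text_parts.append(seg)
                self.pos += len(seg)
                continue
            surface, label = seg[0], seg[1]
            handle = seg[2] if len(seg) > 2 else f"e{n_ent}"
            n_ent += 1
            mention = EntityMention(
                f"T{len(self.entities) + 1}", label,
                self.pos, self.pos + len(surface), surface,
            )
            self.entities.append(mention)
            handles[handle] = mention
            self.text_parts.append(surface)
            self.pos += len(surface)
        self.sentences.append((start, self.pos))
        self.text_parts.append(sep)
        self.pos += len(sep)
        return handles

    def relate(self, trigger: EntityMention, argument: EntityMention,
               label: RelationLabel) -> None:
        self.relations.append(
            RelationMention(f"R{len(self.relations) + 1}", label, trigger,
                            argument)
        )

    def build(self) -> Document:
        text = "".join(self.text_parts)
        doc = Document(
            doc_id=self.doc_id,
            text=text,
            sentences=list(self.sentences),
            entities=self.entities,
            relations=self.relations,
        )
        tokens = []
        for s, e in doc.sentences:
            tokens.extend(tokenize_punct(text[s:e], offset=s))
        doc.tokens = tokens
        return doc


def _generate_document(doc_id: str, rng: random.Random, pools: _Pools,
                       config: GeneratorConfig) -> Document:
    b = _Builder(doc_id)
    num = rng.randint(1, 999)
    with_substep = rng.random() < config.substep_fraction
    with_satag = rng.random() < config.satag_fraction
    with_yield = rng.random() < config.yield_sentence_fraction

    b.sentence(["EXAMPLE ", (str(num), E.EXAMPLE_LABEL)], sep="\n")
    if with_substep:
        b.sentence(
            ["Synthesis of ", (rng.choice(pools.others), E.OTHER_COMPOUND),
             " and ", (rng.choice(pools.others), E.OTHER_COMPOUND)],
            sep="\n",
        )
        b.sentence(
            [f"{num}.1 ", (rng.choice(pools.products), E.REACTION_PRODUCT)],
            sep="\n",
        )

    # setup sentence: one trigger governing compound and auxiliary roles
    verb = rng.choice(_SETUP_VERBS[:4])
    temp = f"{rng.randrange(20, 130, 5)} °C" if rng.random() < 0.8 else "rt"
    time = rng.choice([f"{rng.randint(1, 48)} h", f"{rng.randint(5, 90)} min",
                       "overnight"])
    h = b.sentence(
        ["A solution of ", (rng.choice(pools.starting), E.STARTING_MATERIAL,
                            "sm"),
         " in ", (rng.choice(pools.solvents), E.SOLVENT, "sol"),
         " was ", (verb, E.REACTION_STEP, "trig"),
         " at ", (temp, E.TEMPERATURE, "temp"),
         " for ", (time, E.TIME, "time"), "."]
    )
    b.relate(h["trig"], h["sm"], RelationLabel.ARG1)
    b.relate(h["trig"], h["sol"], RelationLabel.ARG1)
    b.relate(h["trig"], h["temp"], RelationLabel.ARGM)
    b.relate(h["trig"], h["time"], RelationLabel.ARGM)

    # reagent sentence: second trigger takes no arguments (hard negatives)
    if rng.random() < 0.7:
        h = b.sentence(
            ["The mixture was ", ("treated", E.REACTION_STEP, "trig"),
             " with ", (rng.choice(pools.reagents), E.REAGENT_CATALYST, "rg"),
             " and then ", (rng.choice(_WORKUP_VERBS), E.WORKUP, "wk"),
             " under reduced pressure."]
        )
        b.relate(h["trig"], h["rg"], RelationLabel.ARG1)

    # workup sentence: two triggers each governing their own compound
    if with_satag:
        h = b.sentence(
            ["The residue was ", ("dissolved", E.WORKUP, "dis"),
             " in ", (rng.choice(pools.solvents), E.SOLVENT, "sol"),
             " and ", ("washed", E.WORKUP, "wash"),
             " with sat. aq. ", (rng.choice(_SALTS), E.OTHER_COMPOUND, "salt"),
             "."]
        )
        b.relate(h["dis"], h["sol"], RelationLabel.ARG1)
        b.relate(h["dis"], h["salt"], RelationLabel.ARG1)
    elif rng.random() < 0.6:
        h = b.sentence(
            ["The mixture was ", ("washed", E.WORKUP, "wash"),
             " with ", (rng.choice(_SALTS), E.OTHER_COMPOUND, "salt"),
             " and ", ("dried", E.WORKUP, "dry"),
             " over ", (rng.choice(["Na2SO4", "MgSO4"]), E.REAGENT_CATALYST,
                        "des"), "."]
        )
        b.relate(h["wash"], h["salt"], RelationLabel.ARG1)
        b.relate(h["dry"], h["des"], RelationLabel.ARG1)

    # product / yield
    amount = f"{rng.randint(1, 950)} mg"
    percent = f"{rng.randint(5, 99)}%"
    if with_yield:
        h = b.sentence(
            ["The residue was ", ("purified", E.WORKUP, "pur"),
             " by RP-HPLC to give ",
             (rng.choice(pools.products), E.REACTION_PRODUCT, "prod"), "."]
        )
        b.relate(h["pur"], h["prod"], RelationLabel.ARG1)
        hy = b.sentence(
            ["Yield: ", (amount, E.YIELD_OTHER, "amt"),
             " (", (percent, E.YIELD_PERCENT, "pct"), " of theory)."]
        )
        b.relate(h["pur"], hy["amt"], RelationLabel.ARGM)
        b.relate(h["pur"], hy["pct"], RelationLabel.ARGM)
    else:
        h = b.sentence(
            ["The residue was ", ("purified", E.WORKUP, "pur"),
             " by column chromatography to give ",
             (rng.choice(pools.products), E.REACTION_PRODUCT, "prod"),
             " (", (amount, E.YIELD_OTHER, "amt"),
             ", ", (percent, E.YIELD_PERCENT, "pct"), ")."]
        )
        b.relate(h["pur"], h["prod"], RelationLabel.ARG1)
        b.relate(h["pur"], h["amt"], RelationLabel.ARGM)
        b.relate(h["pur"], h["pct"], RelationLabel.ARGM)

    return b.build()


def generate_corpus(config: GeneratorConfig | None = None) -> list[Document]:
    """Generate a deterministic corpus of annotated synthetic snippets."""
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(config.seed)
    pools = _Pools.build(rng, config.lexicon_size)
    docs = []
    for i in range(config.n_documents):
        docs.append(
            _generate_document(f"synth{i:04d}", rng, pools, config)
        )
    return docs


def corpus_stats(docs: Sequence[Document]) -> dict:
    """Entity counts per label, relation counts per type triple, size totals."""
    entity_counts = {label.value: 0 for label in EntityLabel}
    relation_counts: dict[str, int] = {}
    n_sentences = 0
    n_tokens = 0
    for doc in docs:
        n_sentences += len(doc.sentences)
        n_tokens += len(doc.tokens)
        for ent in doc.entities:
            entity_counts[ent.label.value] += 1
        for rel in doc.relations:
            key = "|".join([rel.label.value, rel.trigger.label.value,
                            rel.argument.label.value])
            relation_counts[key] = relation_counts.get(key, 0) + 1
    return {
        "n_documents": len(docs),
        "n_sentences": n_sentences,
        "n_tokens": n_tokens,
        "entity_counts": entity_counts,
        "relation_counts": dict(sorted(relation_counts.items())),
    }


def write_split_corpus(
    docs: Sequence[Document],
    directory: str | Path,
    split: tuple[float, float, float] = (0.6, 0.15, 0.25),
) -> dict[str, list[Document]]:
    """Write <id>.txt/<id>.ann pairs into train/dev/test subdirectories."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    directory = Path(directory)
    n = len(docs)
    n_train = round(n * split[0])
    n_dev = round(n * split[1])
    parts = {
        "train": list(docs[:n_train]),
        "dev": list(docs[n_train : n_train + n_dev]),
        "test": list(docs[n_train + n_dev :]),
    }
    for name, subset in parts.items():
        subdir = directory / name
        subdir.mkdir(parents=True, exist_ok=True)
        for doc in subset:
            write_document_pair(doc, subdir)
    return parts
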