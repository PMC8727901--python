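"""End-to-end cascade: NER -> NER rules -> relation extraction -> relation rules.

Entities are predicted first and relations are classified over the predicted
entities, so entity errors propagate (the cascade property: end-to-end
relation F1 never exceeds relation F1 computed on gold entities).  Training
produces three artifacts — subword vocabulary, tagger model, relation
classifier — plus a manifest recording the config hash, seeds and corpus
statistics, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import evaluation, relations, rules, synthetic, tagging
from .preprocess import SubwordVocabulary, build_vocabulary, tokenize_document
from .standoff import Document, read_corpus_dir, write_corpus_dir

logger = logging.getLogger("chemrext")


@dataclass
class PipelineConfig:
    work_dir: str = "chemrext_run"
    # generator
    n_documents: int = 200
    generator_seed: int = 0
    substep_fraction: float = 0.3
    satag_fraction: float = 0.2
    yield_sentence_fraction: float = 0.3
    # tokenizer
    vocab_size: int = 2000
    # tagger
    tagger_backend: str = "perceptron"
    tagger_seed: int = 0
    tagger_epochs: int = 8
    # relation classifier
    classifier_seed: int = 0
    classifier_threshold: float = 0.5
    # rules
    relabel_headings: bool = True
    trim_example: bool = True
    trim_compound: bool = True
    merge_satag: bool = True
    link_yield: bool = True
    satag_strategy: str = "nearest"
    # evaluation
    eval_mode: str = "exact"

    def rule_config(self) -> rules.RuleConfig:
        return rules.RuleConfig(
            relabel_headings=self.relabel_headings,
            trim_example=self.trim_example,
            trim_compound=self.trim_compound,
            merge_satag=self.merge_satag,
            link_yield=self.link_yield,
            satag_strategy=self.satag_strategy,
        )

    def hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")


@dataclass
class TrainedPipeline:
    vocab: SubwordVocabulary
    tagger: tagging.TaggerModel
    classifier: relations.RelationClassifier
    manifest: dict = field(default_factory=dict)


def prepare_documents(docs: Sequence[Document]) -> list[Document]:
    """Ensure sentences and tokens are populated (in place)."""
    for doc in docs:
        if not doc.tokens:
            tokenize_document(doc)
    return list(docs)


def train_pipeline(
    train_docs: Sequence[Document], config: PipelineConfig | None = None
) -> TrainedPipeline:
    config = config or PipelineConfig()
    train_docs = prepare_documents(train_docs)

    t0 = time.perf_counter()
    vocab = build_vocabulary(train_docs, max_size=config.vocab_size)
    logger.info("vocabulary: %d pieces (%.2fs)", len(vocab.entries),
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    tagger = tagging.train_tagger(
        train_docs,
        tagging.TaggerConfig(
            backend=config.tagger_backend,
            seed=config.tagger_seed,
            epochs=config.tagger_epochs,
        ),
    )
    logger.info("tagger trained on %d documents (%.2fs)", len(train_docs),
                time.perf_counter() - t0)

    t0 = time.perf_counter()
    labeled = []
    for doc in train_docs:
        labeled.extend(relations.gold_candidate_labels(doc))
    classifier = relations.train_classifier(
        labeled,
        relations.ClassifierConfig(
            seed=config.classifier_seed, threshold=config.classifier_threshold
        ),
    )
    logger.info("relation classifier trained on %d candidates (%.2fs)",
                len(labeled), time.perf_counter() - t0)

    manifest = {
        "config_hash": config.hash(),
        "config": asdict(config),
        "seeds": {
            "generator": config.generator_seed,
            "tagger": config.tagger_seed,
            "classifier": config.classifier_seed,
        },
        "n_train_documents": len(train_docs),
        "n_relation_candidates": len(labeled),
        "corpus_stats": synthetic.corpus_stats(train_docs),
    }
    return TrainedPipeline(vocab, tagger, classifier, manifest)


def save_pipeline(pipe: TrainedPipeline, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pipe.vocab.save(directory / "vocab.txt")
    pipe.tagger.save(directory / "tagger.json")
    pipe.classifier.save(directory / "classifier.json")
    (directory / "manifest.json").write_text(
        json.dumps(pipe.manifest, indent=2, sort_keys=True), encoding="utf-8"
    )


def load_pipeline(directory: str | Path) -> TrainedPipeline:
    directory = Path(directory)
    for name in ("vocab.txt", "tagger.json", "classifier.json"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing pipeline artifact {name} "
                                    f"in {directory}")
    manifest_path = directory / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text(encoding="utf-8"))
        if manifest_path.exists() else {}
    )
    return TrainedPipeline(
        vocab=SubwordVocabulary.load(directory / "vocab.txt"),
        tagger=tagging.TaggerModel.load(directory / "tagger.json"),
        classifier=relations.RelationClassifier.load(
            directory / "classifier.json"
        ),
        manifest=manifest,
    )


def predict_document(
    pipe: TrainedPipeline,
    doc: Document,
    rule_config: rules.RuleConfig | None = None,
) -> tuple[Document, list[rules.RuleTrace]]:
    """Run the cascade on one document's raw text."""
    pred = Document(doc_id=doc.doc_id, text=doc.text)
    tokenize_document(pred)
    pred.entities = tagging.predict_entities(pipe.tagger, pred)
    traces: list[rules.RuleTrace] = []
    if rule_config is not None:
        pred, ner_traces = rules.apply_ner_rules(pred, rule_config)
        traces.extend(ner_traces)
    pred.relations = relations.predict_relations(pipe.classifier, pred)
    if rule_config is not None:
        pred, rel_traces = rules.apply_relation_rules(pred, rule_config)
        traces.extend(rel_traces)
    for trace in traces:
        logger.debug("rule trace: %s", trace.to_tsv())
    return pred, traces


def predict_corpus(
    pipe: TrainedPipeline,
    docs: Sequence[Document],
    rule_config: rules.RuleConfig | None = None,
) -> list[Document]:
    t0 = time.perf_counter()
    out = [predict_document(pipe, doc, rule_config)[0] for doc in docs]
    n_ent = sum(len(d.entities) for d in out)
    n_rel = sum(len(d.relations) for d in out)
    logger.info(
        "predicted %d documents: %d entities, %d relations (%.2fs)",
        len(out), n_ent, n_rel, time.perf_counter() - t0,
    )
    return out


def evaluate_corpus(
    gold_docs: Sequence[Document], pred_docs: Sequence[Document]
) -> dict[str, evaluation.EvalReport]:
    """NER and relation reports in both exact and relaxed modes."""
    reports = {}
    for task in ("ner", "end_to_end"):
        for mode in evaluation.MODES:
            reports[f"{task}_{mode}"] = evaluation.score(
                gold_docs, pred_docs, task=task, mode=mode
            )
    return reports


def run_all(config: PipelineConfig) -> dict[str, evaluation.EvalReport]:
    """generate -> split -> train -> predict -> evaluate, under one config."""
    work = Path(config.work_dir)
    corpus = synthetic.generate_corpus(
        synthetic.GeneratorConfig(
            n_documents=config.n_documents,
            seed=config.generator_seed,
            substep_fraction=config.substep_fraction,
            satag_fraction=config.satag_fraction,
            yield_sentence_fraction=config.yield_sentence_fraction,
        )
    )
    parts = synthetic.write_split_corpus(corpus, work / "corpus")
    pipe = train_pipeline(parts["train"] + parts["dev"], config)
    save_pipeline(pipe, work / "models")
    test_docs = parts["test"]
    pred_docs = predict_corpus(pipe, test_docs, config.rule_config())
    write_corpus_dir(pred_docs, work / "predictions")
    reports = evaluate_corpus(test_docs, pred_docs)
    report_dir = work / "reports"
    report_dir.mkdir(parents=True, exist_ok=True)
    for name, report in reports.items():
        (report_dir / f"{name}.json").write_text(report.to_json(),
                                                 encoding="utf-8")
        logger.info("%s overall F1 = %.4f", name, report.overall.f1)
    return reports


def load_gold_and_predict(
    pipe: TrainedPipeline,
    input_dir: str | Path,
    output_dir: str | Path,
    rule_config: rules.RuleConfig | None,
) -> list[Document]:
    docs = read_corpus_dir(input_dir)
    preds = predict_corpus(pipe, docs, rule_config)
    write_corpus_dir(preds, output_dir)
    return preds
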