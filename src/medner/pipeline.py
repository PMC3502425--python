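"""End-to-end experiment orchestration.

Runs the full comparison the package exists for: fit the rule-based, SVM
and CRF systems, combine them with the three voting strategies, and score
everything with exact-match chunk evaluation — either under k-fold
cross-validation (counts pooled across folds before computing micro
scores) or on one fixed train/test split — plus pairwise approximate
randomization tests between all systems.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (
    Document,
    EntityMention,
    Sentence,
    encode_bio,
    read_annotations,
    tokenize,
)
from .ensemble import SystemOutput, VotingConfig, ensemble_predict
from .evaluation import (
    EvalCounts,
    EvalReport,
    RandTestResult,
    approximate_randomization,
    chunk_counts,
    make_folds,
    scores,
)
from .features import FeatureConfig
from .learners import CRFTagger, SVMConfig, SVMTagger
from .rules import Lexicon, PatternRule, load_default_patterns, rule_tag
from .synthetic import SynthConfig, SyntheticCorpus, generate_corpus

log = logging.getLogger("medner")

SINGLE_SYSTEMS = ("rule", "crf", "svm")
STRATEGIES = ("majority", "local_crf", "local_svm")


@dataclass
class ExperimentConfig:
    synth: SynthConfig | None = None
    corpus_dir: str | None = None
    fcfg: FeatureConfig = dc_field(default_factory=FeatureConfig)
    svm_cfg: SVMConfig = dc_field(default_factory=SVMConfig)
    crf_l2: float = 1.0
    crf_max_iter: int = 200
    strategies: tuple[str, ...] = STRATEGIES
    mode: str = "crossval"  # crossval | fixed
    k: int = 10
    train_fraction: float = 0.75
    seed: int = 0
    sigtest_n: int = 1000
    run_sigtests: bool = True
    ranking_sample: int = 30  # train docs scored to rank systems for voting

    def __post_init__(self) -> None:
        if self.mode not in ("crossval", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.synth is None and self.corpus_dir is None:
            raise ValueError("need a synthetic config or a corpus directory")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {unknown}")


@dataclass
class LoadedCorpus:
    documents: list[Document]
    gold_by_doc: dict[str, list[EntityMention]]
    lexicon: Lexicon


@dataclass
class ExperimentResult:
    reports: dict[str, EvalReport]
    counts: dict[str, EvalCounts]
    sigtests: dict[tuple[str, str], RandTestResult]
    fold_reports: list[dict[str, EvalReport]]
    predictions: dict[str, dict[str, list[EntityMention]]]  # system -> doc -> mentions
    gold_by_doc: dict[str, list[EntityMention]]
    manifest: dict

    def table(self) -> str:
        lines = []
        for name in [*SINGLE_SYSTEMS, *STRATEGIES]:
            if name in self.reports:
                lines.append(self.reports[name].to_table(name))
        return "\n".join(lines)


def load_corpus_dir(corpus_dir: str | Path) -> LoadedCorpus:
    """Read notes/*.txt, gold/*.ann and lexicon.tsv from a corpus directory."""
    root = Path(corpus_dir)
    docs: list[Document] = []
    gold: dict[str, list[EntityMention]] = {}
    for note in sorted((root / "notes").glob("*.txt")):
        doc_id = note.stem
        doc = tokenize(note.read_text(), doc_id)
        docs.append(doc)
        ann = root / "gold" / f"{doc_id}.ann"
        mentions: list[EntityMention] = []
        if ann.exists():
            for ev in read_annotations(ann.read_text(), doc_id):
                mentions.extend(ev.mentions)
        gold[doc_id] = mentions
    lex_path = root / "lexicon.tsv"
    lexicon = Lexicon.from_file(lex_path)
    return LoadedCorpus(docs, gold, lexicon)


def load_corpus(cfg: ExperimentConfig) -> LoadedCorpus:
    if cfg.synth is not None:
        corpus = generate_corpus(cfg.synth)
        return LoadedCorpus(corpus.documents, corpus.gold_by_doc, corpus.lexicon)
    return load_corpus_dir(cfg.corpus_dir)


def doc_labeled_sentences(
    doc: Document, gold: Sequence[EntityMention]
) -> list[tuple[Sentence, list[str]]]:
    """Align gold mentions to sentences and BIO-encode them."""
    out = []
    for sent in doc.sentences:
        span = {t.position for t in sent.tokens}
        ms = [m for m in gold if tuple(m.start) in span]
        out.append((sent, encode_bio(sent, ms)))
    return out


class _FoldRun:
    """Fit all systems on the train docs, predict the test docs."""

    def __init__(
        self,
        cfg: ExperimentConfig,
        lexicon: Lexicon,
        patterns: Sequence[PatternRule],
        train: Sequence[Document],
        test: Sequence[Document],
        gold_by_doc: dict[str, list[EntityMention]],
    ) -> None:
        self.cfg = cfg
        self.gold_by_doc = gold_by_doc
        t0 = time.time()
        # rule tagger output (semantic tags + standalone mentions), all docs
        self._rule: dict[str, tuple[list[list[str]], list[EntityMention]]] = {
            d.doc_id: rule_tag(d, lexicon, patterns) for d in [*train, *test]
        }
        training: list[tuple[Sentence, list[str]]] = []
        sem_tags: list[list[str]] = []
        for doc in train:
            tags = self._rule[doc.doc_id][0]
            for (sent, labels), tg in zip(
                doc_labeled_sentences(doc, gold_by_doc[doc.doc_id]), tags
            ):
                training.append((sent, labels))
                sem_tags.append(tg)
        log.info("fitting SVM on %d sentences", len(training))
        self.svm = SVMTagger(cfg.svm_cfg, cfg.fcfg).fit(training, sem_tags)
        log.info("fitting CRF on %d sentences", len(training))
        self.crf = CRFTagger(cfg.fcfg, l2=cfg.crf_l2,
                             max_iter=cfg.crf_max_iter).fit(training, sem_tags)
        log.info("fold fitted in %.1fs", time.time() - t0)
        self.train, self.test = list(train), list(test)

    def predict_docs(
        self, docs: Sequence[Document]
    ) -> tuple[list[Sentence], dict[str, SystemOutput], dict[str, dict[str, list[EntityMention]]]]:
        """Aligned per-sentence outputs and per-doc mentions per system."""
        sentences: list[Sentence] = []
        labels: dict[str, list[list[str]]] = {s: [] for s in SINGLE_SYSTEMS}
        mentions: dict[str, dict[str, list[EntityMention]]] = {
            s: {} for s in SINGLE_SYSTEMS
        }
        from .corpus import decode_bio

        for doc in docs:
            tags, rule_mentions = self._rule[doc.doc_id]
            mentions["rule"][doc.doc_id] = list(rule_mentions)
            for s in SINGLE_SYSTEMS:
                mentions[s].setdefault(doc.doc_id, [])
            for sent, tg in zip(doc.sentences, tags):
                sentences.append(sent)
                rule_labels = encode_bio(
                    sent,
                    [
                        m
                        for m in rule_mentions
                        if tuple(m.start) in {t.position for t in sent.tokens}
                    ],
                )
                labels["rule"].append(rule_labels)
                svm_labels = self.svm.predict(sent, tg)
                crf_labels = self.crf.predict(sent, tg)
                labels["svm"].append(svm_labels)
                labels["crf"].append(crf_labels)
                mentions["svm"][doc.doc_id].extend(decode_bio(sent, svm_labels))
                mentions["crf"][doc.doc_id].extend(decode_bio(sent, crf_labels))
        outputs = {s: SystemOutput(s, labels[s]) for s in SINGLE_SYSTEMS}
        return sentences, outputs, mentions

    def ranking(self, rng: np.random.Generator) -> tuple[str, ...]:
        """Rank systems by micro-F on a sample of the training docs."""
        sample = self.train
        if len(sample) > self.cfg.ranking_sample:
            idx = rng.choice(len(sample), size=self.cfg.ranking_sample,
                             replace=False)
            sample = [sample[int(i)] for i in sorted(idx)]
        _, _, mentions = self.predict_docs(sample)
        f_by_sys = {}
        for s in SINGLE_SYSTEMS:
            counts = EvalCounts()
            for doc in sample:
                counts.add(
                    chunk_counts(
                        self.gold_by_doc[doc.doc_id], mentions[s][doc.doc_id]
                    )
                )
            f_by_sys[s] = scores(counts).micro_f
        return tuple(sorted(SINGLE_SYSTEMS, key=lambda s: -f_by_sys[s]))


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the configured experiment end to end (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    loaded = load_corpus(cfg)
    patterns = load_default_patterns()
    docs = loaded.documents
    if cfg.mode == "crossval":
        folds = make_folds(docs, cfg.k, cfg.seed)
    else:
        order = np.random.default_rng(cfg.seed).permutation(len(docs))
        n_train = max(1, int(round(cfg.train_fraction * len(docs))))
        train = [docs[i] for i in sorted(order[:n_train].tolist())]
        test = [docs[i] for i in sorted(order[n_train:].tolist())]
        folds = [(train, test)]

    systems = [*SINGLE_SYSTEMS, *cfg.strategies]
    counts: dict[str, EvalCounts] = {s: EvalCounts() for s in systems}
    predictions: dict[str, dict[str, list[EntityMention]]] = {
        s: {} for s in systems
    }
    fold_reports: list[dict[str, EvalReport]] = []
    rankings = []
    for fi, (train, test) in enumerate(folds):
        log.info("fold %d/%d: %d train, %d test docs",
                 fi + 1, len(folds), len(train), len(test))
        run = _FoldRun(cfg, loaded.lexicon, patterns, train, test,
                       loaded.gold_by_doc)
        ranking = run.ranking(rng) if "majority" in cfg.strategies else \
            ("crf", "svm", "rule")
        rankings.append(ranking)
        sentences, outputs, mentions = run.predict_docs(test)
        for strat in cfg.strategies:
            vcfg = VotingConfig(strategy=strat, ranking=ranking)
            _, voted_mentions = ensemble_predict(
                sentences, list(outputs.values()), vcfg
            )
            by_doc: dict[str, list[EntityMention]] = {
                d.doc_id: [] for d in test
            }
            for m in voted_mentions:
                by_doc[m.doc_id].append(m)
            mentions[strat] = by_doc
        fold_rep: dict[str, EvalReport] = {}
        for s in systems:
            fold_counts = EvalCounts()
            for doc in test:
                c = chunk_counts(
                    loaded.gold_by_doc[doc.doc_id], mentions[s][doc.doc_id]
                )
                fold_counts.add(c)
                predictions[s][doc.doc_id] = mentions[s][doc.doc_id]
            counts[s].add(fold_counts)
            fold_rep[s] = scores(fold_counts)
        fold_reports.append(fold_rep)

    reports = {s: scores(counts[s]) for s in systems}
    sigtests: dict[tuple[str, str], RandTestResult] = {}
    if cfg.run_sigtests:
        test_gold = {
            d: loaded.gold_by_doc[d] for d in predictions[systems[0]]
        }
        for a, b in itertools.combinations(systems, 2):
            sigtests[(a, b)] = approximate_randomization(
                predictions[a], predictions[b], test_gold,
                n=cfg.sigtest_n, seed=cfg.seed,
            )
    manifest = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "k": cfg.k if cfg.mode == "crossval" else None,
        "train_fraction": cfg.train_fraction if cfg.mode == "fixed" else None,
        "n_docs": len(docs),
        "feature_config": cfg.fcfg.to_dict(),
        "svm": dataclasses.asdict(cfg.svm_cfg),
        "crf": {"l2": cfg.crf_l2, "max_iter": cfg.crf_max_iter},
        "rankings": [list(r) for r in rankings],
        "strategies": list(cfg.strategies),
    }
    return ExperimentResult(
        reports=reports,
        counts=counts,
        sigtests=sigtests,
        fold_reports=fold_reports,
        predictions=predictions,
        gold_by_doc=loaded.gold_by_doc,
        manifest=manifest,
    )


def ablation_grid(window: int = 2) -> list[tuple[str, FeatureConfig]]:
    """The 10-row feature-ablation design over the six SVM families."""
    rows = [
        ("words", dict()),
        ("words+history", dict(use_history=True)),
        ("words+morph", dict(use_morph=True)),
        ("words+pos", dict(use_pos=True)),
        ("words+ortho", dict(use_ortho=True)),
        ("words+semantic", dict(use_semantic=True)),
        ("words+history+morph", dict(use_history=True, use_morph=True)),
        ("words+history+morph+pos",
         dict(use_history=True, use_morph=True, use_pos=True)),
        ("words+history+morph+pos+ortho",
         dict(use_history=True, use_morph=True, use_pos=True, use_ortho=True)),
        ("all", dict(use_history=True, use_morph=True, use_pos=True,
                     use_ortho=True, use_semantic=True)),
    ]
    base = dict(use_word=True, use_pos=False, use_morph=False,
                use_ortho=False, use_semantic=False, use_history=False,
                use_bigram=False, window=window)
    return [(name, FeatureConfig(**{**base, **flags})) for name, flags in rows]
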