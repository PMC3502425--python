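"""Seeded generator of discharge-summary-like corpora with gold annotations.

The generator emulates the two sentence styles of medication text in
hospital notes — terse list-style entries ("Percocet 1-2 Tablets p.o. Q 4
prn,") and narrative prose ("The patient was started on lasix 40 mg orally
daily for edema.") — with gold field mentions aligned to token boundaries.
Default per-sentence field rates keep the corpus class imbalance
proportional to the published field counts of the underlying challenge
corpus (medication ≫ dosage ≈ frequency ≈ mode ≫ reason ≫ duration), so
duration and reason stay the scarce, hard fields.  The narrative templates
deliberately include the confusable pair "as needed" (frequency) versus
"as long as needed" (duration).

A label corrupter simulates imperfect systems with controlled per-field
deletion, boundary-shift, type-confusion and spurious-mention rates, which
is the measurement surface for the evaluator and ensemble tests.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the config, so corpora are byte-identical across runs and
platforms for a given seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    AnnotationLine,
    Document,
    EntityMention,
    FIELD_CODES,
    Sentence,
    encode_bio,
    tokenize,
    write_annotations,
)
from .ensemble import SystemOutput
from .rules import Lexicon

# Per-sentence expected mention counts; proportions follow the published
# field counts 12773 : 4791 : 3552 : 4342 : 597 : 1534.
DEFAULT_FIELD_RATES: dict[str, float] = {
    "m": 0.80,
    "do": 0.30,
    "mo": 0.22,
    "f": 0.27,
    "du": 0.04,
    "r": 0.10,
}

DRUG_NAMES: tuple[str, ...] = (
    "Percocet", "Lasix", "Tylenol", "Aspirin", "Metformin", "Lisinopril",
    "Atenolol", "Metoprolol", "Amlodipine", "Losartan", "Furosemide",
    "Simvastatin", "Atorvastatin", "Warfarin", "Coumadin", "Heparin",
    "Plavix", "Digoxin", "Amiodarone", "Insulin", "Glipizide",
    "Levothyroxine", "Prednisone", "Omeprazole", "Protonix", "Zofran",
    "Colace", "Senna", "Amoxicillin", "Ceftriaxone", "Azithromycin",
    "Ciprofloxacin", "Levofloxacin", "Doxycycline", "Vancomycin",
    "Flagyl", "Morphine", "Oxycodone", "Tramadol", "Dilaudid",
    "Gabapentin", "Neurontin", "Keppra", "Dilantin", "Zoloft", "Prozac",
    "Celexa", "Lexapro", "Trazodone", "Seroquel", "Haldol", "Ativan",
    "Valium", "Xanax", "Klonopin", "Ambien", "Albuterol", "Atrovent",
    "Singulair", "Flomax", "Allopurinol", "Baclofen", "Methotrexate",
    "Nitroglycerin", "Caltrate plus D", "ferrous sulfate", "folic acid",
    "vitamin d", "potassium chloride", "fish oil",
)

REASON_TERMS: tuple[str, ...] = (
    "fever", "pain", "chest pain", "dizziness", "nausea", "vomiting",
    "constipation", "insomnia", "anxiety", "agitation", "hypertension",
    "diabetes", "infection", "cough", "wheezing", "edema", "headache",
    "reflux", "seizures", "rare angina", "frequent PVCs",
)

DOSAGE_TEMPLATES: tuple[str, ...] = (
    "{n} mg", "{n} mcg", "{n} ml", "1-2 Tablets", "one tablet",
    "two tablets", "{n} units", "two puffs", "0.4 mg", "{n} meq",
)

MODE_TERMS: tuple[str, ...] = (
    "p.o.", "orally", "IV", "intravenous", "topical", "sublingual",
    "by mouth", "subcutaneously",
)

FREQ_TEMPLATES: tuple[str, ...] = (
    "prn", "as needed", "Q 4 prn", "b.i.d.", "t.i.d.", "daily",
    "three times a day", "once a day", "x3 before meal", "every morning",
)

DURATION_TEMPLATES: tuple[str, ...] = (
    "x10 days", "for ten days", "for {n} days", "3-day course",
    "for a month", "as long as needed", "during spring break",
    "until the symptom disappears", "for two weeks",
)

_FILLERS: tuple[str, ...] = (
    "The patient was discharged home in stable condition.",
    "Follow up with your primary care doctor next week.",
    "Labs were reviewed and are noted in the chart.",
    "The hospital stay was otherwise uneventful.",
    "Vital signs remained within normal limits.",
    "The family was updated at the bedside.",
)

_SYLLABLES = ("al", "bex", "cor", "dal", "dex", "fen", "gat", "lor", "mab",
              "nex", "pril", "quin", "rex", "sol", "tan", "vir", "zol", "mir")


@dataclass
class SynthConfig:
    """Shape of the generated corpus; all randomness derives from ``seed``."""

    n_notes: int = 100
    sentences_per_note: tuple[int, int] = (3, 8)
    list_fraction: float = 0.6
    field_rates: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_FIELD_RATES)
    )
    lexicon_size: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")
        if not 0 <= self.list_fraction <= 1:
            raise ValueError("list_fraction must be in [0, 1]")
        for c, r in self.field_rates.items():
            if c not in FIELD_CODES or r < 0:
                raise ValueError(f"bad field rate {c}={r}")
        rm = self.field_rates.get("m", 0.0)
        for c, r in self.field_rates.items():
            if c != "m" and rm > 0 and r > rm:
                raise ValueError("non-medication rates may not exceed the m rate")


@dataclass
class CorruptionConfig:
    """Controlled error process applied to gold labels, per field.

    Scalar rates apply to every field; dicts override per field code.
    Confusion rows map a gold field to substitute-field probabilities and
    must sum to ≤ 1.
    """

    deletion: float | Mapping[str, float] = 0.0
    boundary: float | Mapping[str, float] = 0.0
    confusion: Mapping[str, Mapping[str, float]] = dc_field(default_factory=dict)
    spurious: float = 0.0
    seed: int = 0

    def rate(self, which: str, code: str) -> float:
        val = getattr(self, which)
        r = val.get(code, 0.0) if isinstance(val, Mapping) else float(val)
        if not 0 <= r <= 1:
            raise ValueError(f"{which} rate for {code} out of [0, 1]")
        return r

    def __post_init__(self) -> None:
        for code, row in self.confusion.items():
            if code not in FIELD_CODES:
                raise ValueError(f"unknown field {code} in confusion matrix")
            if sum(row.values()) > 1 + 1e-9:
                raise ValueError(f"confusion row for {code} sums over 1")
        if not 0 <= self.spurious <= 1:
            raise ValueError("spurious rate out of [0, 1]")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    events: dict[str, list[AnnotationLine]]  # doc_id -> medication events
    lexicon: Lexicon
    config: SynthConfig

    @property
    def gold_by_doc(self) -> dict[str, list[EntityMention]]:
        return {
            d: [m for ev in evs for m in ev.mentions]
            for d, evs in self.events.items()
        }

    def gold_mentions(self) -> list[EntityMention]:
        return [m for evs in self.events.values() for ev in evs for m in ev.mentions]

    def labeled_sentences(self) -> list[tuple[Sentence, list[str]]]:
        """(sentence, gold BIO labels) pairs across the corpus."""
        out = []
        gold = self.gold_by_doc
        for doc in self.documents:
            for sent in doc.sentences:
                span = {t.position for t in sent.tokens}
                ms = [m for m in gold[doc.doc_id] if tuple(m.start) in span]
                out.append((sent, encode_bio(sent, ms)))
        return out


def _pseudo_drug(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 4))
    parts = [_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), size=k)]
    return "".join(parts).capitalize()


def _build_lexicon(cfg: SynthConfig, rng: np.random.Generator) -> tuple[list[str], Lexicon]:
    drugs = list(DRUG_NAMES)
    while len(drugs) < cfg.lexicon_size:
        cand = _pseudo_drug(rng)
        if cand not in drugs:
            drugs.append(cand)
    if len(drugs) > cfg.lexicon_size:
        idx = rng.choice(len(drugs), size=cfg.lexicon_size, replace=False)
        drugs = [drugs[int(i)] for i in sorted(idx)]
    entries = {d: "m" for d in drugs}
    entries.update({r: "r" for r in REASON_TERMS})
    return drugs, Lexicon(entries)


def _fill_template(tpl: str, rng: np.random.Generator) -> str:
    return tpl.replace("{n}", str(int(rng.choice([5, 10, 20, 25, 40, 50, 100]))))


class _SentenceBuilder:
    def __init__(self) -> None:
        self.tokens: list[str] = []
        self.spans: list[tuple[str, int, int]] = []  # (field, i0, i1)

    def add(self, text: str, field: str | None = None) -> None:
        toks = text.split()
        i0 = len(self.tokens)
        self.tokens.extend(toks)
        if field is not None:
            self.spans.append((field, i0, len(self.tokens) - 1))

    def finish_period(self) -> None:
        if self.tokens and not self.tokens[-1][-1] in ".,:;":
            self.tokens[-1] += "."


def _event_fields(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, bool]:
    rm = cfg.field_rates["m"] or 1.0
    return {
        c: bool(rng.random() < cfg.field_rates[c] / rm)
        for c in FIELD_CODES
        if c != "m"
    }


def _build_sentence(
    cfg: SynthConfig,
    rng: np.random.Generator,
    drugs: Sequence[str],
    n_events: int,
    list_style: bool,
) -> _SentenceBuilder:
    sb = _SentenceBuilder()
    if n_events == 0:
        sb.add(str(rng.choice(_FILLERS)))
        return sb
    if not list_style:
        sb.add(str(rng.choice([
            "The patient was started on",
            "He was continued on",
            "She will take",
            "The team restarted",
        ])))
    for _ in range(n_events):
        inc = _event_fields(cfg, rng)
        sb.add(str(rng.choice(drugs)), "m")
        if inc["do"]:
            sb.add(_fill_template(str(rng.choice(DOSAGE_TEMPLATES)), rng), "do")
        if inc["mo"]:
            sb.add(str(rng.choice(MODE_TERMS)), "mo")
        if inc["f"]:
            sb.add(str(rng.choice(FREQ_TEMPLATES)), "f")
        if inc["du"]:
            sb.add(_fill_template(str(rng.choice(DURATION_TEMPLATES)), rng), "du")
        if inc["r"]:
            sb.add("for")
            sb.add(str(rng.choice(REASON_TERMS)), "r")
    if not list_style:
        sb.finish_period()
    return sb


def generate_corpus(cfg: SynthConfig) -> SyntheticCorpus:
    """Generate notes, gold events and the generating lexicon.

    Deterministic per seed; every mention is non-overlapping and aligned
    to whitespace token boundaries, and notes re-tokenize to the sentences
    the generator produced (sentences are single lines separated by blank
    lines).
    """
    rng = np.random.default_rng(cfg.seed)
    drugs, lexicon = _build_lexicon(cfg, rng)
    rate_m = cfg.field_rates["m"]
    documents: list[Document] = []
    events: dict[str, list[AnnotationLine]] = {}
    for ni in range(cfg.n_notes):
        doc_id = f"note{ni:04d}"
        lo, hi = cfg.sentences_per_note
        n_sent = int(rng.integers(lo, hi + 1))
        lines: list[str] = []
        sent_spans: list[tuple[int, _SentenceBuilder, str]] = []
        for _ in range(n_sent):
            n_events = int(rate_m) + int(rng.random() < rate_m - int(rate_m))
            list_style = bool(rng.random() < cfg.list_fraction)
            sb = _build_sentence(cfg, rng, drugs, n_events, list_style)
            if lines:
                lines.append("")  # blank line separates sentences
            line_no = len(lines) + 1  # 1-based
            lines.append(" ".join(sb.tokens))
            sent_spans.append(
                (line_no, sb, "list" if list_style else "narrative")
            )
        raw = "\n".join(lines)
        doc = tokenize(raw, doc_id)
        documents.append(doc)
        evs: list[AnnotationLine] = []
        for line_no, sb, style in sent_spans:
            # group spans into per-medication events: an event starts at m
            current: list[EntityMention] = []
            for code, i0, i1 in sb.spans:
                mention = EntityMention(
                    field=code,
                    start=(line_no, i0),
                    end=(line_no, i1),
                    text=" ".join(sb.tokens[i0 : i1 + 1]),
                    doc_id=doc_id,
                )
                if code == "m" and current:
                    evs.append(AnnotationLine(current, style))
                    current = []
                current.append(mention)
            if current:
                evs.append(AnnotationLine(current, style))
        events[doc_id] = evs
    return SyntheticCorpus(documents, events, lexicon, cfg)


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict:
    """Write notes, gold ``.ann`` files, the lexicon and a manifest."""
    out = Path(out_dir)
    (out / "notes").mkdir(parents=True, exist_ok=True)
    (out / "gold").mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        (out / "notes" / f"{doc.doc_id}.txt").write_text("\n".join(doc.lines) + "\n")
        (out / "gold" / f"{doc.doc_id}.ann").write_text(
            write_annotations(corpus.events[doc.doc_id], doc)
            if corpus.events[doc.doc_id]
            else ""
        )
    (out / "lexicon.tsv").write_text(corpus.lexicon.to_text())
    manifest = {
        "n_notes": corpus.config.n_notes,
        "seed": corpus.config.seed,
        "list_fraction": corpus.config.list_fraction,
        "field_rates": corpus.config.field_rates,
        "lexicon_size": corpus.config.lexicon_size,
        "sentences_per_note": list(corpus.config.sentences_per_note),
    }
    import yaml

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Label corrupter


def _spans_from_labels(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    spans = []
    i = 0
    while i < len(labels):
        if labels[i] == "O":
            i += 1
            continue
        code = labels[i].split("-", 1)[1]
        j = i + 1
        while j < len(labels) and labels[j] == f"I-{code}":
            j += 1
        spans.append((code, i, j - 1))
        i = j
    return spans


def corrupt(
    gold_labels: Sequence[Sequence[str]],
    cfg: CorruptionConfig,
    system_id: str = "corrupted",
) -> SystemOutput:
    """Simulate an imperfect system by perturbing gold label sequences.

    Per mention, in order: deletion (→ all O), else type confusion per the
    configured row, else a ±1-token boundary shift of the mention end (kept
    only when it stays inside the sentence and clear of other mentions).
    Per sentence, a spurious 1–2 token mention of a random field is
    inserted over O tokens with the configured probability.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[list[str]] = []
    for labels in gold_labels:
        labels = list(labels)
        n = len(labels)
        spans = _spans_from_labels(labels)
        orig = [(i0, i1) for _, i0, i1 in spans]
        kept: list[tuple[str, int, int]] = []
        for si, (code, i0, i1) in enumerate(spans):
            if rng.random() < cfg.rate("deletion", code):
                continue
            new_code = code
            row = cfg.confusion.get(code, {})
            if row:
                u = rng.random()
                acc = 0.0
                for alt, p in row.items():
                    acc += p
                    if u < acc:
                        new_code = alt
                        break
            if rng.random() < cfg.rate("boundary", code):
                delta = int(rng.choice([-1, 1]))
                j0, j1 = i0, i1 + delta
                if j1 < j0:
                    j0, j1 = i0 + delta, i1  # shrink from the left instead
                others = [sp for k, sp in enumerate(orig) if k != si]
                ok = (
                    0 <= j0 <= j1 < n
                    and not any(a <= j1 and j0 <= b for a, b in others)
                    and not any(a <= j1 and j0 <= b for _, a, b in kept)
                )
                if ok:
                    i0, i1 = j0, j1
            kept.append((new_code, i0, i1))
        if rng.random() < cfg.spurious:
            occupied = [False] * n
            for _, a, b in kept:
                for k in range(a, b + 1):
                    occupied[k] = True
            free = [k for k in range(n) if not occupied[k]]
            if free:
                start = int(rng.choice(free))
                length = int(rng.integers(1, 3))
                end = start
                if length == 2 and start + 1 < n and not occupied[start + 1]:
                    end = start + 1
                kept.append((str(rng.choice(FIELD_CODES)), start, end))
        new_labels = ["O"] * n
        for code, a, b in kept:
            new_labels[a] = f"B-{code}"
            for k in range(a + 1, b + 1):
                new_labels[k] = f"I-{code}"
        out.append(new_labels)
    return SystemOutput(system_id, out)
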