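"""Lexicon- and pattern-based medication field tagger.

A deliberately compact stand-in for a full rule-based medication extraction
engine: a drug/term lexicon matched greedily longest-first, plus ordered
token-sequence patterns for the shape-like fields (dosage, mode, frequency,
duration).  It produces two things the rest of the package consumes: a
per-token semantic-tag sequence (a feature family for the learners) and
standalone field mentions (the rule-based system in the ensemble).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document, EntityMention, FIELD_CODES, Sentence

NO_TAG = "O"


def normalize_token(text: str) -> str:
    """Lower-case and strip trailing clause punctuation for matching.

    A trailing period is stripped only when the token has no internal
    period, so dotted abbreviations like ``p.o.`` keep their shape.
    """
    t = text.lower().rstrip(",;:")
    if t.endswith(".") and "." not in t[:-1]:
        t = t[:-1]
    return t


@dataclass
class Lexicon:
    """Case-insensitive multi-token phrase table, phrase → field code."""

    entries: dict[str, str]
    max_phrase_len: int = 1

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for phrase, code in self.entries.items():
            key = " ".join(normalize_token(p) for p in phrase.split())
            if not key:
                raise ValueError("empty lexicon phrase")
            if code not in FIELD_CODES:
                raise ValueError(f"unknown field code {code!r} for {phrase!r}")
            norm[key] = code
        self.entries = norm
        self.max_phrase_len = max(
            (len(k.split()) for k in norm), default=1
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Lexicon":
        return cls(dict(pairs))

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def from_text(cls, text: str) -> "Lexicon":
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            phrase, _, code = line.partition("\t")
            pairs.append((phrase, code.strip()))
        return cls.from_pairs(pairs)

    def to_text(self) -> str:
        return "".join(f"{p}\t{c}\n" for p, c in sorted(self.entries.items()))


@dataclass
class PatternRule:
    """A token-sequence pattern: one regex per token, matched against
    normalized token texts.  Higher priority shadows lower on overlap."""

    name: str
    field: str
    priority: int
    pattern: str  # space-separated per-token regexes
    token_res: list[re.Pattern] = dc_field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.field not in FIELD_CODES:
            raise ValueError(f"unknown field code {self.field!r}")
        self.token_res = [
            re.compile(p, re.IGNORECASE) for p in self.pattern.split()
        ]
        if not self.token_res:
            raise ValueError(f"rule {self.name!r} has an empty pattern")


def load_patterns(text: str) -> list[PatternRule]:
    """Parse ``name<TAB>field<TAB>priority<TAB>pattern`` lines."""
    rules = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        name, code, prio, pattern = line.split("\t", 3)
        rules.append(PatternRule(name, code, int(prio), pattern))
    return rules


def load_default_lexicon() -> Lexicon:
    data = resources.files("medner.data").joinpath("lexicon.tsv").read_text()
    return Lexicon.from_text(data)


def load_default_patterns() -> list[PatternRule]:
    data = resources.files("medner.data").joinpath("patterns.tsv").read_text()
    return load_patterns(data)


Span = tuple[int, int]  # inclusive token-index span within one sentence


def lexicon_lookup(sentence: Sentence, lexicon: Lexicon) -> list[tuple[Span, str]]:
    """Greedy longest-match left-to-right lexicon scan (case-insensitive)."""
    norm = [normalize_token(t) for t in sentence.texts]
    n = len(norm)
    out: list[tuple[Span, str]] = []
    i = 0
    while i < n:
        hit = None
        for length in range(min(lexicon.max_phrase_len, n - i), 0, -1):
            key = " ".join(norm[i : i + length])
            code = lexicon.entries.get(key)
            if code is not None:
                hit = ((i, i + length - 1), code)
                break
        if hit is None:
            i += 1
        else:
            out.append(hit)
            i = hit[0][1] + 1
    return out


def apply_patterns(
    sentence: Sentence, rules: Sequence[PatternRule]
) -> list[tuple[Span, str]]:
    """Scan each rule left-to-right, higher priority first; a claimed token
    cannot be re-used by a lower-priority (or later) match."""
    norm = [normalize_token(t) for t in sentence.texts]
    n = len(norm)
    claimed = [False] * n
    out: list[tuple[Span, str]] = []
    for rule in sorted(rules, key=lambda r: (-r.priority, r.name)):
        k = len(rule.token_res)
        i = 0
        while i + k <= n:
            window = norm[i : i + k]
            if not any(claimed[i : i + k]) and all(
                tr.fullmatch(w) for tr, w in zip(rule.token_res, window)
            ):
                out.append(((i, i + k - 1), rule.field))
                for j in range(i, i + k):
                    claimed[j] = True
                i += k
            else:
                i += 1
    out.sort(key=lambda sp: sp[0])
    return out


def _merge_spans(
    lex: list[tuple[Span, str]], pat: list[tuple[Span, str]], n: int
) -> list[tuple[Span, str]]:
    # Precedence: non-medication patterns > medication lexicon entries >
    # other lexicon entries > medication patterns.  Drug names are a closed
    # vocabulary (dictionary territory); the other five fields are
    # shape-like (pattern territory).
    taken = [False] * n
    placed: list[tuple[Span, str]] = []

    def try_place(span: Span, code: str) -> None:
        a, b = span
        if not any(taken[a : b + 1]):
            placed.append((span, code))
            for j in range(a, b + 1):
                taken[j] = True

    for span, code in pat:
        if code != "m":
            try_place(span, code)
    for span, code in lex:
        if code == "m":
            try_place(span, code)
    for span, code in lex:
        if code != "m":
            try_place(span, code)
    for span, code in pat:
        if code == "m":
            try_place(span, code)
    placed.sort(key=lambda sp: sp[0])
    return placed


def rule_tag(
    document: Document,
    lexicon: Lexicon,
    rules: Sequence[PatternRule],
) -> tuple[list[list[str]], list[EntityMention]]:
    """Tag a note: per-sentence semantic-tag sequences plus field mentions.

    The semantic tags (field code or ``O`` per token) feed the learners'
    semantic-tag feature family; the mentions are the standalone rule-based
    system's output.
    """
    all_tags: list[list[str]] = []
    mentions: list[EntityMention] = []
    for sent in document.sentences:
        lex = lexicon_lookup(sent, lexicon)
        pat = apply_patterns(sent, rules)
        spans = _merge_spans(lex, pat, len(sent))
        tags = [NO_TAG] * len(sent)
        for (a, b), code in spans:
            for j in range(a, b + 1):
                tags[j] = code
            mentions.append(
                EntityMention(
                    field=code,
                    start=sent.tokens[a].position,
                    end=sent.tokens[b].position,
                    text=" ".join(t.text for t in sent.tokens[a : b + 1]),
                    doc_id=document.doc_id or None,
                )
            )
        all_tags.append(tags)
    return all_tags, mentions


def semantic_tags_for(
    documents: Sequence[Document],
    lexicon: Lexicon,
    rules: Sequence[PatternRule],
) -> dict[str, list[list[str]]]:
    """Semantic-tag sequences per doc_id, for feeding the learners."""
    return {
        doc.doc_id: rule_tag(doc, lexicon, rules)[0] for doc in documents
    }
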