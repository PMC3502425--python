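"""Data model and I/O for line-oriented clinical notes with medication annotations.

A note is plain text, one document per file; tokens are addressed by
``(line, offset)`` where ``line`` is 1-based and ``offset`` is the 0-based
whitespace-token index within that line.  Six medication-related field types
are annotated: medication (``m``), dosage (``do``), mode (``mo``), frequency
(``f``), duration (``du``) and reason (``r``).  The per-token labeling scheme
is BIO, which for six field types yields 13 labels (6 B + 6 I + O).

This module provides the tokenizer, the annotation-file dialect
(reader/writer) and the BIO encoder/decoder that every other module builds
on.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

#: The six field codes, in canonical order.
FIELD_CODES: tuple[str, ...] = ("m", "do", "mo", "f", "du", "r")

FIELD_NAMES: dict[str, str] = {
    "m": "medication",
    "do": "dosage",
    "mo": "mode",
    "f": "frequency",
    "du": "duration",
    "r": "reason",
}

#: The 13 BIO labels.  This tuple order (B before I per field, O last) is
#: also the deterministic tie-break order used by the learners and voters.
BIO_LABELS: tuple[str, ...] = tuple(
    f"{p}-{c}" for c in FIELD_CODES for p in ("B", "I")
) + ("O",)

LABEL_RANK: dict[str, int] = {lab: i for i, lab in enumerate(BIO_LABELS)}

OUTSIDE = "O"


def label_field(label: str) -> str | None:
    """Field code of a BIO label, or None for O."""
    if label == OUTSIDE:
        return None
    return label.split("-", 1)[1]


class AnnotationParseError(ValueError):
    """Raised when an annotation line does not follow the dialect."""


@dataclass(frozen=True)
class Token:
    """One whitespace-delimited token with its position in the note."""

    text: str
    line: int  # 1-based line number
    offset: int  # 0-based token index within the line

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise ValueError(f"token text must be non-empty, no whitespace: {self.text!r}")
        if self.line < 1 or self.offset < 0:
            raise ValueError(f"bad token position {(self.line, self.offset)}")

    @property
    def position(self) -> tuple[int, int]:
        return (self.line, self.offset)


@dataclass
class Sentence:
    """An ordered run of tokens; the unit sequence for labeling."""

    tokens: list[Token]
    doc_id: str = ""

    def __post_init__(self) -> None:
        pos = [t.position for t in self.tokens]
        if pos != sorted(pos):
            raise ValueError("tokens must be in reading order")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class Document:
    """A note: raw lines plus the sentence segmentation over them."""

    doc_id: str
    lines: list[str]
    sentences: list[Sentence]

    @property
    def tokens(self) -> list[Token]:
        return [t for s in self.sentences for t in s.tokens]


@dataclass(frozen=True)
class EntityMention:
    """One annotated field: a contiguous token span of a single field type.

    ``start``/``end`` are inclusive ``(line, offset)`` positions; ``text``
    is the whitespace-joined covered tokens.  ``doc_id`` keys the mention to
    its note when mentions from several notes are pooled.
    """

    field: str
    start: tuple[int, int]
    end: tuple[int, int]
    text: str
    doc_id: str | None = None

    def __post_init__(self) -> None:
        if self.field not in FIELD_CODES:
            raise ValueError(f"unknown field code {self.field!r}")
        if tuple(self.start) > tuple(self.end):
            raise ValueError(f"mention start {self.start} after end {self.end}")

    def key(self) -> tuple:
        """Identity for exact-match chunk evaluation."""
        return (self.doc_id, self.field, self.start, self.end)


@dataclass
class AnnotationLine:
    """One medication event: up to one mention per field, plus the
    list/narrative flag (``ln``), which is preserved but never evaluated."""

    mentions: list[EntityMention]
    style: str = "narrative"


# ---------------------------------------------------------------------------
# Tokenization


def _sentence_final(text: str) -> bool:
    # A token ends a sentence if it ends with "." and has no internal "."
    # (so dotted abbreviations like "p.o." or "q.d." never split).
    return text.endswith(".") and "." not in text[:-1]


def tokenize(raw_note: str, doc_id: str = "") -> Document:
    """Split a note into sentences of position-addressed tokens.

    Tokens are whitespace-delimited with punctuation left attached
    ("prn," is one token).  Sentences break at blank lines and after a
    period-terminated token that either ends its line or is followed by an
    uppercase-initial token.
    """
    lines = raw_note.split("\n")
    flat: list[Token] = []
    last_on_line: list[bool] = []
    for li, line in enumerate(lines, start=1):
        parts = line.split()
        for oi, part in enumerate(parts):
            flat.append(Token(part, li, oi))
            last_on_line.append(oi == len(parts) - 1)

    sentences: list[Sentence] = []
    cur: list[Token] = []

    def flush() -> None:
        if cur:
            sentences.append(Sentence(list(cur), doc_id))
            cur.clear()

    for i, tok in enumerate(flat):
        cur.append(tok)
        nxt = flat[i + 1] if i + 1 < len(flat) else None
        if nxt is None:
            flush()
            continue
        # blank line strictly between this token's line and the next token's
        blank_between = any(
            not lines[k].strip() for k in range(tok.line, nxt.line - 1)
        )
        if blank_between:
            flush()
        elif _sentence_final(tok.text) and (
            last_on_line[i] or (nxt.text[:1].isupper())
        ):
            flush()
    return Document(doc_id, lines, sentences)


# ---------------------------------------------------------------------------
# Annotation dialect

_FIELD_PART = re.compile(
    r'^(?P<code>[a-z]+)="(?P<text>[^"]*)"'
    r"(?: (?P<l1>\d+):(?P<t1>\d+) (?P<l2>\d+):(?P<t2>\d+))?$"
)


def parse_annotation_line(line: str, doc_id: str | None = None) -> AnnotationLine:
    """Parse one medication event in the ``m="…" L:T L:T||…||ln="…"`` dialect.

    Absent fields appear as ``x="nm"``; the ``ln`` flag carries the
    list/narrative style.  Returns the mentions plus the style flag.
    """
    mentions: list[EntityMention] = []
    style = "narrative"
    col = 0
    for part in line.rstrip("\n").split("||"):
        m = _FIELD_PART.match(part)
        if m is None:
            raise AnnotationParseError(
                f"malformed annotation part at column {col}: {part!r}"
            )
        code = m.group("code")
        if code == "ln":
            style = m.group("text")
        elif code in FIELD_CODES:
            text = m.group("text")
            if text != "nm":
                if m.group("l1") is None:
                    raise AnnotationParseError(
                        f"field {code!r} at column {col} has text but no span"
                    )
                mentions.append(
                    EntityMention(
                        field=code,
                        start=(int(m.group("l1")), int(m.group("t1"))),
                        end=(int(m.group("l2")), int(m.group("t2"))),
                        text=text,
                        doc_id=doc_id,
                    )
                )
        else:
            raise AnnotationParseError(
                f"unknown field code {code!r} at column {col}"
            )
        col += len(part) + 2
    return AnnotationLine(mentions, style)


def write_annotation_line(
    mentions: Sequence[EntityMention],
    style: str = "narrative",
    document: Document | None = None,
) -> str:
    """Emit one medication event in the annotation dialect.

    Fields are written in the canonical order m, do, mo, f, du, r followed
    by ``ln``; surface text is lower-cased; absent fields become ``x="nm"``.
    If *document* is given, every span must resolve to tokens whose joined
    text equals the mention text case-insensitively.
    """
    by_field: dict[str, EntityMention] = {}
    for m in mentions:
        if m.field in by_field:
            raise ValueError(f"duplicate field {m.field!r} in one event")
        by_field[m.field] = m
    if document is not None:
        index = {t.position: t for t in document.tokens}
        for m in by_field.values():
            covered = [
                t.text
                for t in document.tokens
                if m.start <= t.position <= m.end
            ]
            if not covered or m.start not in index or m.end not in index:
                raise ValueError(f"mention span {m.start}..{m.end} not in document")
            if " ".join(covered).lower() != m.text.lower():
                raise ValueError(
                    f"mention text {m.text!r} does not match document tokens"
                )
    parts = []
    for code in FIELD_CODES:
        m = by_field.get(code)
        if m is None:
            parts.append(f'{code}="nm"')
        else:
            parts.append(
                f'{code}="{m.text.lower()}" '
                f"{m.start[0]}:{m.start[1]} {m.end[0]}:{m.end[1]}"
            )
    parts.append(f'ln="{style}"')
    return "||".join(parts)


def read_annotations(text: str, doc_id: str | None = None) -> list[AnnotationLine]:
    """Parse a whole ``.ann`` file (one event per non-blank line)."""
    return [
        parse_annotation_line(line, doc_id)
        for line in text.split("\n")
        if line.strip()
    ]


def write_annotations(
    events: Iterable[AnnotationLine], document: Document | None = None
) -> str:
    return (
        "\n".join(
            write_annotation_line(ev.mentions, ev.style, document) for ev in events
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# BIO encoding


def encode_bio(sentence: Sentence, mentions: Sequence[EntityMention]) -> list[str]:
    """Label each token: B-x at mention starts, I-x inside, O elsewhere.

    Mentions must lie within the sentence and not overlap.
    """
    index = {t.position: i for i, t in enumerate(sentence.tokens)}
    labels = [OUTSIDE] * len(sentence)
    for m in mentions:
        if tuple(m.start) not in index or tuple(m.end) not in index:
            raise ValueError(f"mention {m} not within sentence")
        i0, i1 = index[tuple(m.start)], index[tuple(m.end)]
        for i in range(i0, i1 + 1):
            if labels[i] != OUTSIDE:
                raise ValueError(f"overlapping mentions at token {i}")
        labels[i0] = f"B-{m.field}"
        for i in range(i0 + 1, i1 + 1):
            labels[i] = f"I-{m.field}"
    return labels


def decode_bio(sentence: Sentence, labels: Sequence[str]) -> list[EntityMention]:
    """Recover mentions from a BIO label sequence.

    Maximal runs ``B-x (I-x)*`` become one mention; an orphan ``I-x`` (not
    preceded by B-x or I-x) starts a new mention of x, so any label
    sequence over the 13-label set is decodable.
    """
    if len(labels) != len(sentence):
        raise ValueError(
            f"labels length {len(labels)} != sentence length {len(sentence)}"
        )
    for lab in labels:
        if lab not in LABEL_RANK:
            raise ValueError(f"unknown label {lab!r}")
    mentions: list[EntityMention] = []
    i = 0
    n = len(labels)
    while i < n:
        lab = labels[i]
        if lab == OUTSIDE:
            i += 1
            continue
        code = label_field(lab)
        j = i + 1
        while j < n and labels[j] == f"I-{code}":
            j += 1
        mentions.append(
            EntityMention(
                field=code,
                start=sentence.tokens[i].position,
                end=sentence.tokens[j - 1].position,
                text=" ".join(t.text for t in sentence.tokens[i:j]),
                doc_id=sentence.doc_id or None,
            )
        )
        i = j
    return mentions


def with_doc(mention: EntityMention, doc_id: str) -> EntityMention:
    return dataclasses.replace(mention, doc_id=doc_id)
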