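"""Token-level features for the sequence labelers.

Six feature families are supported: surface word, part of speech,
morphology (affixes), orthographic shape, semantic tag (from the rule-based
tagger), and the history feature (the label assigned to the preceding
token, used only by the greedy SVM decoder).  All families except history
are extracted over a symmetric context window (default half-width 2);
feature names carry the relative offset so that e.g. ``w[-1]=lasix`` and
``w[0]=lasix`` are distinct.

Label-bigram features are not token features: they are transition features
owned by the CRF learner and merely switched on here (``use_bigram``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

from .corpus import Sentence

BOUNDARY = "<S>"  # out-of-window-bounds marker
BOS_LABEL = "<BOS>"  # history marker at sentence start


@dataclass
class FeatureConfig:
    """Which feature families are on, and the window geometry.

    ``window`` is the context half-width (positions −w…+w); ``affix_len``
    is the maximum prefix/suffix length for the morphology family.
    """

    use_word: bool = True
    use_pos: bool = True
    use_morph: bool = True
    use_ortho: bool = True
    use_semantic: bool = True
    use_history: bool = True
    use_bigram: bool = True
    window: int = 2
    affix_len: int = 3

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.affix_len < 1:
            raise ValueError("affix_len must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)

    def to_kv(self) -> str:
        """Flat ``key = value`` serialization."""
        return "".join(f"{k} = {v}\n" for k, v in self.to_dict().items())

    @classmethod
    def from_kv(cls, text: str) -> "FeatureConfig":
        d: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), v.strip()
            d[k] = v.lower() == "true" if v.lower() in ("true", "false") else int(v)
        return cls(**d)


def affixes(word: str, max_len: int = 3) -> tuple[list[str], list[str]]:
    """Prefixes and suffixes of lengths 1..min(max_len, len(word))."""
    if not word:
        raise ValueError("empty word has no affixes")
    k = min(max_len, len(word))
    prefixes = [word[:i] for i in range(1, k + 1)]
    suffixes = [word[-i:] for i in range(1, k + 1)]
    return prefixes, suffixes


# ---------------------------------------------------------------------------
# Orthography: 21 mutually ordered shape categories, first match wins.
# The category table is this package's normative definition; it emphasizes
# the digit/percent/range shapes that matter for medication text (dosages
# like "100", "0.5%", "1-2").

_ORTHO_TABLE: list[tuple[str, Callable[[str], bool]]] = [
    ("ALL_DIGITS", lambda w: bool(re.fullmatch(r"\d{3,}", w))),
    ("SINGLE_DIGIT", lambda w: bool(re.fullmatch(r"\d", w))),
    ("DOUBLE_DIGIT", lambda w: bool(re.fullmatch(r"\d\d", w))),
    ("REAL_NUMBER", lambda w: bool(re.fullmatch(r"\d+\.\d+", w))),
    ("PERCENT", lambda w: bool(re.fullmatch(r"\d+(\.\d+)?%", w))),
    ("RANGE", lambda w: bool(re.fullmatch(r"\d+-\d+", w))),
    ("DIGIT_SLASH", lambda w: bool(re.fullmatch(r"\d+/\d+", w))),
    ("ALPHA_DIGIT", lambda w: bool(re.fullmatch(r"[A-Za-z]+\d+", w))),
    ("DIGIT_ALPHA", lambda w: bool(re.fullmatch(r"\d+[A-Za-z]+", w))),
    ("DOTTED_ABBREV", lambda w: bool(re.fullmatch(r"(?:[A-Za-z]\.){2,}", w))),
    ("ALL_CAPS", lambda w: bool(re.fullmatch(r"[A-Z]{2,}", w))),
    ("INIT_CAP", lambda w: bool(re.fullmatch(r"[A-Z][a-z]+", w))),
    ("ALL_LOWER", lambda w: bool(re.fullmatch(r"[a-z]+", w))),
    ("MIXED_CASE", lambda w: bool(re.fullmatch(r"[A-Za-z]+", w))),
    ("HYPHENATED", lambda w: "-" in w and any(c.isalnum() for c in w)),
    ("SLASH_WORD", lambda w: "/" in w and any(c.isalnum() for c in w)),
    ("PUNCT_ONLY", lambda w: not any(c.isalnum() for c in w)),
    ("HAS_PAREN", lambda w: "(" in w or ")" in w),
    ("ENDS_COMMA", lambda w: w.endswith(",")),
    ("ENDS_PERIOD", lambda w: w.endswith(".")),
    ("OTHER", lambda w: True),
]

ORTHO_CATEGORIES: tuple[str, ...] = tuple(name for name, _ in _ORTHO_TABLE)
assert len(ORTHO_CATEGORIES) == 21


def orthographic_class(word: str) -> str:
    """The single orthographic category of *word* (first match wins)."""
    if not word:
        raise ValueError("empty word has no orthographic class")
    for name, pred in _ORTHO_TABLE:
        if pred(word):
            return name
    raise AssertionError("unreachable: OTHER is total")


# ---------------------------------------------------------------------------
# POS tagging: a deterministic ~20-rule fallback tagger (Penn-style tags).
# A toolkit tagger can be plugged in via the ``backend`` argument.

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "and": "CC", "or": "CC", "but": "CC",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "for": "IN",
    "with": "IN", "by": "IN", "to": "TO", "from": "IN", "until": "IN",
    "during": "IN", "per": "IN", "before": "IN", "after": "IN", "as": "IN",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
    "will": "MD", "should": "MD", "may": "MD", "can": "MD", "must": "MD",
    "not": "RB", "no": "DT",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP",
}

_POS_RULES: list[tuple[re.Pattern, str]] = [
    (re.compile(r"[.!?]"), "."),
    (re.compile(r","), ","),
    (re.compile(r"[:;]"), ":"),
    (re.compile(r"[^\w]+"), "SYM"),
    (re.compile(r"\d+(\.\d+)?%?,?\.?"), "CD"),
    (re.compile(r"\d+-\d+,?"), "CD"),
    (re.compile(r"\d+/\d+"), "CD"),
    (re.compile(r"\d+(st|nd|rd|th)"), "JJ"),
    (re.compile(r"(?:[A-Za-z]\.){2,}"), "NN"),  # dotted abbreviations
    (re.compile(r"[A-Za-z]+[a-z]ly,?\.?"), "RB"),
    (re.compile(r"[A-Za-z]+ing,?\.?"), "VBG"),
    (re.compile(r"[A-Za-z]+ed,?\.?"), "VBD"),
    (re.compile(r"[A-Za-z]*[a-rt-z]s,?\.?"), "NNS"),  # plural, not -ss
    (re.compile(r"[A-Z]+,?\.?"), "NN"),
    (re.compile(r"[A-Z][A-Za-z]*,?\.?"), "NN"),
]


def _tag_word(word: str) -> str:
    tag = _CLOSED_CLASS.get(word.lower().rstrip(".,;:") or word.lower())
    if tag is not None:
        return tag
    for pat, t in _POS_RULES:
        if pat.fullmatch(word):
            return t
    return "NN"


def pos_tag(
    sentence: Sentence | Sequence[str],
    backend: Callable[[list[str]], list[str]] | None = None,
) -> list[str]:
    """One POS label per token; pluggable backend, deterministic default."""
    words = sentence.texts if isinstance(sentence, Sentence) else list(sentence)
    if backend is not None:
        try:
            tags = list(backend(words))
        except Exception as exc:  # noqa: BLE001 - report which backend failed
            raise RuntimeError(f"POS backend {backend!r} failed: {exc}") from exc
        if len(tags) != len(words):
            raise RuntimeError(f"POS backend {backend!r} returned wrong length")
        return tags
    return [_tag_word(w) for w in words]


# ---------------------------------------------------------------------------
# Windowed token features


def token_features(
    sentence: Sentence,
    i: int,
    semantic_tags: Sequence[str] | None = None,
    prev_labels: Sequence[str] | None = None,
    cfg: FeatureConfig | None = None,
    _pos: Sequence[str] | None = None,
) -> dict[str, float]:
    """Binary feature dict for position *i* of *sentence*.

    For every in-window position, the enabled families emit features tagged
    with the relative offset; out-of-bounds positions emit one boundary
    marker each.  The history feature (enabled family + non-None
    ``prev_labels``) is the label at i−1, or a begin-of-sentence marker.
    """
    cfg = cfg or FeatureConfig()
    n = len(sentence)
    if not 0 <= i < n:
        raise IndexError(f"position {i} out of range for sentence of {n}")
    if semantic_tags is not None and len(semantic_tags) != n:
        raise ValueError("semantic_tags not aligned to sentence")
    pos_tags = _pos if _pos is not None else (
        pos_tag(sentence) if cfg.use_pos else None
    )
    feats: dict[str, float] = {}
    words = sentence.texts
    for d in range(-cfg.window, cfg.window + 1):
        j = i + d
        if j < 0 or j >= n:
            feats[f"bnd[{d:+d}]={BOUNDARY}"] = 1.0
            continue
        w = words[j]
        if cfg.use_word:
            feats[f"w[{d:+d}]={w}"] = 1.0
        if cfg.use_pos:
            feats[f"pos[{d:+d}]={pos_tags[j]}"] = 1.0
        if cfg.use_morph:
            pres, sufs = affixes(w, cfg.affix_len)
            for p in pres:
                feats[f"pre[{d:+d}]={p}"] = 1.0
            for s in sufs:
                feats[f"suf[{d:+d}]={s}"] = 1.0
        if cfg.use_ortho:
            feats[f"ortho[{d:+d}]={orthographic_class(w)}"] = 1.0
        if cfg.use_semantic and semantic_tags is not None:
            feats[f"sem[{d:+d}]={semantic_tags[j]}"] = 1.0
    if cfg.use_history and prev_labels is not None:
        prev = prev_labels[i - 1] if i > 0 else BOS_LABEL
        feats[f"hist={prev}"] = 1.0
    return feats


def sentence_features(
    sentence: Sentence,
    semantic_tags: Sequence[str] | None = None,
    prev_labels: Sequence[str] | None = None,
    cfg: FeatureConfig | None = None,
) -> list[dict[str, float]]:
    """Feature dicts for every position, sharing one POS pass."""
    cfg = cfg or FeatureConfig()
    pos_tags = pos_tag(sentence) if cfg.use_pos else None
    return [
        token_features(sentence, i, semantic_tags, prev_labels, cfg, _pos=pos_tags)
        for i in range(len(sentence))
    ]
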