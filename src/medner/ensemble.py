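"""Token-level voting over the outputs of the rule, SVM and CRF systems.

Three strategies are implemented:

* ``majority`` — a label agreed by a strict majority of the systems wins;
  with no majority, the label of the highest-ranked system (by overall
  training micro-F, supplied as the ``ranking``) is used.
* ``local_crf`` — duration and reason labels come from the CRF, everything
  else from the SVM (the CRF is locally trusted for the two hard,
  non-phrase-like fields).
* ``local_svm`` — the mirror image: duration and reason from the SVM, the
  rest from the CRF.

Voting can splice BIO-invalid transitions, so every strategy is followed by
:func:`repair_bio`, which rewrites orphan ``I-x`` labels to ``B-x`` and
makes the output decodable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

from .corpus import (
    BIO_LABELS,
    EntityMention,
    LABEL_RANK,
    OUTSIDE,
    Sentence,
    decode_bio,
    label_field,
)

LOCAL_FIELDS_DEFAULT = frozenset({"du", "r"})


@dataclass
class SystemOutput:
    """Per-sentence label sequences of one system over a corpus."""

    system_id: str
    labels: list[list[str]]


@dataclass
class VotingConfig:
    strategy: str = "majority"  # majority | local_crf | local_svm
    ranking: tuple[str, ...] = ("crf", "svm", "rule")
    local_fields: frozenset[str] = LOCAL_FIELDS_DEFAULT

    def __post_init__(self) -> None:
        if self.strategy not in ("majority", "local_crf", "local_svm"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def vote_majority(labels: Mapping[str, str], ranking: Sequence[str]) -> str:
    """Modal label over systems if a strict majority exists; otherwise the
    label of the highest-ranked system."""
    if not labels:
        raise ValueError("no system labels to vote on")
    counts = Counter(labels.values())
    lab, cnt = max(
        counts.items(), key=lambda kv: (kv[1], -LABEL_RANK[kv[0]])
    )
    if 2 * cnt > len(labels):
        return lab
    for sys_id in ranking:
        if sys_id in labels:
            return labels[sys_id]
    raise ValueError("ranking covers none of the voting systems")


def vote_local(primary_label: str, fallback_label: str,
               local_fields: frozenset[str] = LOCAL_FIELDS_DEFAULT) -> str:
    """Primary system's label when it predicts a locally-trusted field;
    otherwise the fallback system's label."""
    if label_field(primary_label) in local_fields:
        return primary_label
    return fallback_label


def repair_bio(labels: Sequence[str]) -> list[str]:
    """Rewrite orphan I-x (no preceding B-x/I-x) to B-x; all else unchanged."""
    out: list[str] = []
    for i, lab in enumerate(labels):
        if lab.startswith("I-"):
            code = label_field(lab)
            prev = out[i - 1] if i > 0 else OUTSIDE
            if prev not in (f"B-{code}", f"I-{code}"):
                lab = f"B-{code}"
        out.append(lab)
    return out


def is_valid_bio(labels: Sequence[str]) -> bool:
    """True iff every I-x is preceded by B-x or I-x of the same field."""
    prev = OUTSIDE
    for lab in labels:
        if lab.startswith("I-"):
            code = label_field(lab)
            if prev not in (f"B-{code}", f"I-{code}"):
                return False
        prev = lab
    return True


def ensemble_predict(
    sentences: Sequence[Sentence],
    outputs: Sequence[SystemOutput],
    cfg: VotingConfig,
) -> tuple[list[list[str]], list[EntityMention]]:
    """Apply the voting strategy token-by-token, repair BIO, decode mentions.

    All outputs must be aligned to *sentences*; majority voting needs all
    three systems, the local strategies need ``svm`` and ``crf``.
    """
    by_id = {o.system_id: o for o in outputs}
    if len(by_id) != len(outputs):
        raise ValueError("duplicate system_id in outputs")
    for o in outputs:
        if len(o.labels) != len(sentences) or any(
            len(ls) != len(s) for ls, s in zip(o.labels, sentences)
        ):
            raise ValueError(f"output of {o.system_id!r} misaligned to corpus")

    if cfg.strategy == "majority":
        missing = {"rule", "svm", "crf"} - set(by_id)
        if missing:
            raise ValueError(f"majority voting needs all three systems; missing {missing}")
    else:
        missing = {"svm", "crf"} - set(by_id)
        if missing:
            raise ValueError(f"local voting needs svm and crf; missing {missing}")
        primary_id = "crf" if cfg.strategy == "local_crf" else "svm"
        fallback_id = "svm" if cfg.strategy == "local_crf" else "crf"

    voted: list[list[str]] = []
    mentions: list[EntityMention] = []
    for si, sent in enumerate(sentences):
        labs: list[str] = []
        for ti in range(len(sent)):
            if cfg.strategy == "majority":
                labs.append(
                    vote_majority(
                        {sid: by_id[sid].labels[si][ti] for sid in by_id},
                        cfg.ranking,
                    )
                )
            else:
                labs.append(
                    vote_local(
                        by_id[primary_id].labels[si][ti],
                        by_id[fallback_id].labels[si][ti],
                        cfg.local_fields,
                    )
                )
        labs = repair_bio(labs)
        voted.append(labs)
        mentions.extend(decode_bio(sent, labs))
    return voted, mentions
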