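"""Chunk-level evaluation, cross-validation folds, and significance testing.

Scoring is exact-match chunk evaluation in the CoNLL shared-task style: a
predicted mention counts as a true positive only when a gold mention with
the same field type and the same token span exists; precision, recall and
F are reported per field and micro-averaged over all mentions (percentage
scale).

System comparison uses an approximate randomization test: the two systems'
per-document prediction sets are pooled, repeatedly re-partitioned at
random, and the observed micro-F difference is ranked within the shuffled
differences.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Document, EntityMention, FIELD_CODES


@dataclass
class EvalCounts:
    """Per-field true positive / false positive / false negative counts."""

    counts: dict[str, list[int]] = dc_field(
        default_factory=lambda: {c: [0, 0, 0] for c in FIELD_CODES}
    )

    def add(self, other: "EvalCounts") -> "EvalCounts":
        for c in FIELD_CODES:
            for k in range(3):
                self.counts[c][k] += other.counts[c][k]
        return self

    def totals(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.counts.values())
        fp = sum(v[1] for v in self.counts.values())
        fn = sum(v[2] for v in self.counts.values())
        return tp, fp, fn

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in FIELD_CODES], dtype=np.int64)


@dataclass
class EvalReport:
    """Precision/recall/F (percent) per field plus the micro-averaged row."""

    per_field: dict[str, tuple[float, float, float]]
    overall: tuple[float, float, float]

    @property
    def micro_f(self) -> float:
        return self.overall[2]

    def to_table(self, name: str = "") -> str:
        cols = ["ALL", *FIELD_CODES]
        rows = {"ALL": self.overall, **self.per_field}
        lines = [name + "\t" + "\t".join(cols)] if name else ["\t" + "\t".join(cols)]
        for which, label in (("Pre", 0), ("Re", 1), ("F-score", 2)):
            lines.append(
                which + "\t" + "\t".join(f"{rows[c][label]:.2f}" for c in cols)
            )
        return "\n".join(lines)


@dataclass
class RandTestResult:
    """Approximate-randomization outcome for systems A and B.

    ``f_observed`` is micro-F(A) − micro-F(B); ``p_value`` is the raw
    proportion of shuffles with f_i − f ≥ 0; ``p_value_reversed`` is the
    same test with the roles of A and B swapped (the test is one-sided and
    the labeling of the better system as A is a reporting choice).
    """

    f_observed: float
    p_value: float
    p_value_reversed: float
    n: int
    seed: int


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def chunk_counts(
    gold: Sequence[EntityMention], pred: Sequence[EntityMention]
) -> EvalCounts:
    """Exact-match chunk counts: tp iff an identical (doc, field, span)
    mention exists in gold; unmatched predictions are fp, unmatched gold fn."""
    gset = {m.key() for m in gold}
    pset = {m.key() for m in pred}
    if len(gset) != len(gold):
        raise ValueError("duplicate mentions in gold")
    if len(pset) != len(pred):
        raise ValueError("duplicate mentions in predictions")
    out = EvalCounts()
    for m in pred:
        out.counts[m.field][0 if m.key() in gset else 1] += 1
    for m in gold:
        if m.key() not in pset:
            out.counts[m.field][2] += 1
    return out


def scores(counts: EvalCounts) -> EvalReport:
    """Per-field and micro-averaged P/R/F from chunk counts."""
    per_field = {
        c: _prf(*counts.counts[c]) for c in FIELD_CODES
    }
    return EvalReport(per_field=per_field, overall=_prf(*counts.totals()))


def evaluate(gold: Sequence[EntityMention],
             pred: Sequence[EntityMention]) -> EvalReport:
    return scores(chunk_counts(gold, pred))


def _micro_f_from_rows(rows: np.ndarray) -> float:
    tp, fp, fn = rows.sum(axis=0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 200.0 * p * r / (p + r) if p + r else 0.0


def _per_doc_count_rows(
    pred_by_doc: Mapping[str, Sequence[EntityMention]],
    gold_by_doc: Mapping[str, Sequence[EntityMention]],
) -> np.ndarray:
    """One (tp, fp, fn) row per document (entry of the randomization test)."""
    rows = []
    for doc_id in sorted(gold_by_doc):
        c = chunk_counts(gold_by_doc[doc_id], pred_by_doc.get(doc_id, []))
        rows.append(list(c.totals()))
    return np.array(rows, dtype=np.int64)


def group_by_doc(
    mentions: Sequence[EntityMention],
) -> dict[str, list[EntityMention]]:
    out: dict[str, list[EntityMention]] = {}
    for m in mentions:
        out.setdefault(m.doc_id or "", []).append(m)
    return out


def approximate_randomization(
    pred_a: Mapping[str, Sequence[EntityMention]],
    pred_b: Mapping[str, Sequence[EntityMention]],
    gold: Mapping[str, Sequence[EntityMention]],
    n: int = 1000,
    seed: int = 0,
    variant: str = "pool",
) -> RandTestResult:
    """One-sided approximate randomization test on the micro-F difference.

    An *entry* is one document's predicted mention set.  In the ``pool``
    variant the j + k entries of both systems form a superset C; each
    iteration draws j entries from C without replacement as pseudo-A and
    leaves the remainder as pseudo-B.  In the ``swap`` variant each
    document's pair of entries is exchanged between the systems with
    probability one half.  ``p = #(f_i − f ≥ 0) / n`` with no smoothing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if variant not in ("pool", "swap"):
        raise ValueError(f"unknown variant {variant!r}")
    rows_a = _per_doc_count_rows(pred_a, gold)
    rows_b = _per_doc_count_rows(pred_b, gold)
    f_obs = _micro_f_from_rows(rows_a) - _micro_f_from_rows(rows_b)
    rng = np.random.default_rng(seed)
    j = rows_a.shape[0]
    pooled = np.vstack([rows_a, rows_b])
    ge_fwd = 0
    ge_rev = 0
    # antithetic draws: every odd iteration uses the complement of the
    # previous partition (itself a uniform random partition), which halves
    # the estimator variance and makes the symmetric null exact: identical
    # inputs always yield p >= 0.5
    pa = pb = None
    for it in range(n):
        if pa is not None and it % 2 == 1:
            pa, pb = pb, pa
        elif variant == "pool":
            perm = rng.permutation(pooled.shape[0])
            pa, pb = pooled[perm[:j]], pooled[perm[j:]]
        else:
            flip = rng.random(j) < 0.5
            pa = np.where(flip[:, None], rows_b, rows_a)
            pb = np.where(flip[:, None], rows_a, rows_b)
        f_i = _micro_f_from_rows(pa) - _micro_f_from_rows(pb)
        if f_i - f_obs >= 0:
            ge_fwd += 1
        if (-f_i) - (-f_obs) >= 0:
            ge_rev += 1
    return RandTestResult(
        f_observed=f_obs,
        p_value=ge_fwd / n,
        p_value_reversed=ge_rev / n,
        n=n,
        seed=seed,
    )


def make_folds(
    corpus: Sequence[Document], k: int, seed: int = 0
) -> list[tuple[list[Document], list[Document]]]:
    """Seeded random partition into k folds of near-equal size (diff ≤ 1);
    returns (train, test) pairs, each document in exactly one test fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError(f"corpus of {len(corpus)} cannot make {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test_idx = set(folds[i].tolist())
        train = [corpus[j] for j in range(len(corpus)) if j not in test_idx]
        test = [corpus[j] for j in sorted(test_idx)]
        out.append((train, test))
    return out
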