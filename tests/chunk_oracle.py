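"""Independent CoNLL-style chunk evaluator used as a test oracle.

Re-implements the classic shared-task evaluation script's chunk semantics
directly over BIO label columns (start-of-chunk / end-of-chunk tests),
with no use of the package's mention decoding, so the two evaluation paths
are independent.
"""
from __future__ import annotations


def conll_chunks(labels: list[str]) -> list[tuple[str, int, int]]:
    """(type, start, end) chunks per the reference start/end-of-chunk rules."""
    out: list[tuple[str, int, int]] = []
    start = None
    cur_type = ""
    prev_tag, prev_type = "O", ""
    for i, lab in enumerate(list(labels) + ["O"]):
        if lab == "O":
            tag, typ = "O", ""
        else:
            tag, typ = lab.split("-", 1)
        chunk_end = prev_tag != "O" and (tag in ("O", "B") or typ != prev_type)
        chunk_start = tag != "O" and (prev_tag == "O" or tag == "B" or typ != prev_type)
        if chunk_end and start is not None:
            out.append((cur_type, start, i - 1))
            start = None
        if chunk_start:
            start, cur_type = i, typ
        prev_tag, prev_type = tag, typ
    return out


def conll_micro_prf(
    gold_seqs: list[list[str]], pred_seqs: list[list[str]]
) -> tuple[float, float, float]:
    """Micro precision/recall/F (percent) over exact-match chunks."""
    tp = n_pred = n_gold = 0
    for si, (g, p) in enumerate(zip(gold_seqs, pred_seqs, strict=True)):
        gch = {(si, *c) for c in conll_chunks(g)}
        pch = {(si, *c) for c in conll_chunks(p)}
        tp += len(gch & pch)
        n_pred += len(pch)
        n_gold += len(gch)
    prec = 100.0 * tp / n_pred if n_pred else 0.0
    rec = 100.0 * tp / n_gold if n_gold else 0.0
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f
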