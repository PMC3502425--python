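# Methods

`medner` recognizes six types of medication information in hospital
discharge summaries — medication name (m), dosage (do), mode (mo),
frequency (f), duration (du) and reason (r) — as a token-level sequence
labeling problem, and studies whether combining heterogeneous recognizers
by simple voting beats any single recognizer.  This note records the
models, the numerical choices, and what the synthetic evaluation does and
does not show.

## Task representation

Notes are line-oriented plain text.  Tokens are whitespace-delimited with
punctuation left attached (so `prn,` is one token), addressed by a 1-based
line number and a 0-based within-line offset.  Sentences break at blank
lines and after a period-terminated token that ends its line or is
followed by an uppercase-initial token; a token with internal periods
(`p.o.`, `b.i.d.`) never terminates a sentence.  Field mentions are
contiguous token spans of a single type; per-token labels use the BIO
scheme, which for six fields yields 13 labels (6 B + 6 I + O).  Annotation
files carry one medication event per line in the dialect

    m="percocet" 10:0 10:0||do="1-2 tablets" 10:1 10:2||mo=...||ln="list"

with absent fields written as `x="nm"` and the list/narrative flag (`ln`)
preserved but never evaluated.  Offsets are inclusive at both ends.  The
writer lower-cases surface text; the reader re-aligns case-insensitively.

## The three recognizers

**Rule-based tagger.**  A lexicon of drug names and reason terms matched
greedily longest-first (case-insensitive, trailing clause punctuation
stripped) plus ordered token-sequence patterns for the shape-like fields
(dosage, mode, frequency, duration).  Higher-priority patterns shadow
overlapping lower-priority ones; the overlap precedence between lexicon and
patterns is: non-medication patterns, then medication lexicon entries, then
other lexicon entries, then medication patterns — drug names are a closed
vocabulary, the other five fields are shape-like.  The tagger emits both
standalone mentions (the "rule" system) and a per-token semantic-tag
sequence that the learners consume as a feature family, i.e. the rule
system is also cascaded into both statistical models.  The shipped assets
(~230 lexicon entries, 25 patterns) are plain-text data files and are
user-replaceable; in experiments the corpus's own lexicon is used, playing
the role of a dictionary customized to the training data.  This module is
deliberately a compact stand-in for a full medication-extraction engine:
no semantic grammar, section tagging or spell correction.

**SVM tagger.**  One-vs-one multiclass SVM over the 13 labels: n(n−1)/2
pairwise binary classifiers for the n labels present in training (78 when
all 13 occur), polynomial kernel of degree 2 with C = 1.0, over sparse
binary token features in a ±2 context window.  Decoding is greedy
left-to-right: the history feature at position i is the tagger's own
prediction at i−1 (gold labels are used when building training vectors).
Prediction counts pairwise votes explicitly from the pairwise decision
values; vote ties break by the fixed label order (B before I per field in
canonical field order, O last).  No Viterbi search is run over SVM scores.

**Linear-chain CRF.**  The conditional model

    P(y|x) = exp( Σ_{i=1..L} Σ_{k=1..K} w_k f_k(y_{i−1}, y_i, i, x) ) / Z(x)

with indicator feature functions of two kinds: every token feature crossed
with the current label, and label-bigram transition indicators
(y_{i−1}, y_i).  Weights maximize the L2-regularized conditional log
likelihood (regularization strength 1.0 — the natural default where
nothing else is specified), optimized with L-BFGS for at most 200
iterations.  Z(x) is computed by the forward algorithm in log space;
decoding is Viterbi with ties resolving to the canonical label order.  The
chain numerics (`forward_log_partition`, `viterbi_decode`,
`sequence_logscore`) are plain functions over a state-score matrix and a
transition matrix, so tests verify them against exhaustive enumeration of
all |labels|^L sequences on small instances.  Forward–backward passes are
batched over same-length sentences for speed; a gradient check is implicit
in the optimizer's convergence on separable data.

## Feature families

Six families, each switchable for ablation studies: surface word; POS tag;
morphology (all prefixes and suffixes up to 3 characters); orthographic
shape; semantic tag from the rule tagger; history (SVM only — the CRF's
transition features play that role, surfaced as the "bigram" switch).
All families except history are emitted for every position in the ±2
window, tagged with their relative offset; out-of-window-bounds positions
emit a boundary marker.  The feature set of a configuration is a superset
of any configuration with a subset of switches, so ablation grids nest.

The 21 orthographic categories are matched first-wins in a fixed order
(ALL_DIGITS … OTHER, see `features.ORTHO_CATEGORIES`); the table is this
package's normative definition, chosen to emphasize the digit, percent and
range shapes that matter for dosages.  Exactly one category per token.

POS tagging defaults to a deterministic ~20-rule regex tagger
(closed-class lookup, digit/ordinal patterns, suffix heuristics,
capitalization), which keeps tests reproducible with no model downloads; a
general-purpose toolkit tagger can be plugged in through the `backend`
argument of `pos_tag`.

## Ensemble voting

Voting is at the token-label level.  *Majority*: a label emitted by a
strict majority of the three systems wins; with three-way disagreement the
label of the highest-ranked system is used.  The ranking is "overall
F-score" operationalized as a static ordering by micro-F measured on (a
sample of up to 30 of) the training documents, since per-word F-scores are
undefined for unseen words; the ranking is a config input so other
orderings can be exercised.  *Local CRF*: duration and reason labels come
from the CRF, everything else from the SVM — these two fields are scarce
and often not noun phrases ("as long as needed"), and a single model tends
not to win on all six fields.  *Local SVM* is the mirror image.  Every
strategy is followed by a BIO repair that rewrites orphan I-x to B-x, so
ensemble output is always decodable; whether the original systems applied
such a repair after voting is unknowable from their description, so this
convention is fixed here.

## Evaluation

Exact-match chunk evaluation: a predicted mention is correct only if a
gold mention with the same type and token span exists.  Precision, recall
and F (= 2PR/(P+R), zero when undefined) are reported per field and
micro-averaged from summed counts (weights proportional to field sizes).
Cross-validation uses seeded random folds of near-equal size (sizes differ
by at most one); cross-fold scores are computed from counts pooled over
all folds rather than averaging per-fold F — consistent with
micro-averaging over all mentions — and per-fold reports are also kept.

**Approximate randomization.**  For outputs A (j entries) and B (k
entries), an entry being one document's predicted mention set, the
observed difference is f = microF(A) − microF(B); A and B are pooled into
C, each of n iterations draws j entries from C without replacement as
pseudo-A and leaves the rest as pseudo-B, and p = #(f_i − f ≥ 0)/n with no
smoothing, n = 1000 by default.  Per-document pooling is used because it
keeps entries evaluable against gold; the mainstream per-document *swap*
variant is available behind a flag.  The test is one-sided and the
labeling of the better system as A is a reporting choice, so the p-value
for the reversed ordering is always reported alongside.  Under a simulated
null the empirical type-I error at α = 0.05 is consistent with 5% (checked
against the exact binomial interval in the acceptance suite).

## Synthetic corpus

Real annotated discharge summaries of this kind are distributed only under
a data-use agreement, so the package ships a generator instead of data.
Each note is 3–8 single-line sentences separated by blank lines; a
configurable fraction (default 0.6) are list-style prescription lines, the
rest narrative templates.  Default per-sentence field rates (m 0.80,
do 0.30, mo 0.22, f 0.27, du 0.04, r 0.10) keep expected counts
proportional to the published per-field totals of the motivating corpus,
preserving the scarcity of duration and reason.  Entity vocabulary (drug
names incl. generated pseudo-drugs, reason terms) is disjoint from filler
vocabulary, so the corpus is *separable*: a system with the generating
lexicon and covering patterns can in principle reach 100% F.  The
generator returns its own lexicon to make that explicit.

The corrupter turns gold labels into a simulated imperfect system with
per-field deletion, ±1-token boundary-shift and type-confusion rates plus
per-sentence spurious insertions; evaluating corrupted output against gold
recovers the configured rates within sampling error, which is the
package's parameter-recovery check.

What passing on this corpus shows: the pipeline's plumbing, learnability
on clean separable data, the exactness of the voting and evaluation
arithmetic, and the calibration of the significance test.  What it does
not show: performance on real clinical text, which has misspellings,
section structure, ambiguous boundaries, annotation disagreement and
out-of-lexicon drugs.  Published F-scores on the real corpus (around
86–91% depending on system) are therefore not comparable to the near-100%
figures on synthetic data, and reproducing them requires obtaining the
real corpus and running the fixed-split mode on it.

## Problem sizes and determinism

Unit tests run on corpora of tens of notes; the end-to-end acceptance
check uses a 500-note corpus with an 80/20 split, and the acceptance
script a 200-note corpus with a 75/25 split — sizes chosen to exercise
every code path at desk scale.  All randomness (generator, corrupter, fold
assignment, randomization test, ranking subsample) flows through
`numpy.random.default_rng` (PCG64) seeded explicitly, so every run is
reproducible from its manifest.

## Known limitations

- The tokenizer's sentence heuristic mis-splits after abbreviations with a
  single trailing period ("Dr.") followed by a capitalized word.
- One mention per field per medication event in the annotation dialect; no
  overlapping or discontinuous spans, no character-offset standoff.
- The SVM's greedy decoding cannot recover from an early history error;
  no beam or n-best search is provided.
- The rule tagger's coverage is whatever its lexicon and patterns cover;
  it is a deliberately simple stand-in, not a full extraction engine.
- Field-to-medication relation grouping (`ln` lines tie fields to events
  in the files) is preserved in I/O but never predicted or evaluated.
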