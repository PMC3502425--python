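"""The two supervised sequence labelers behind a common contract.

* :class:`SVMTagger` — a one-vs-one multiclass SVM with a polynomial
  kernel (degree 2, C = 1.0 by default), decoded greedily left-to-right
  with the history feature fed the tagger's own previous predictions.
  Per-token prediction is explicit vote counting over the pairwise
  classifiers, with ties broken by the fixed label order.

* :class:`CRFTagger` — a linear-chain conditional random field.  The model
  assigns P(y|x) = exp(Σ_i Σ_k w_k f_k(y_{i-1}, y_i, i, x)) / Z(x) where
  the feature functions are token features crossed with the current label,
  plus label-bigram transition indicators.  Training maximizes the
  L2-regularized conditional log likelihood with L-BFGS; decoding is
  Viterbi; the normalizer Z(x) is computed with the forward algorithm.

Both labelers emit one label per token from the 13-label BIO set and are
deterministic after fitting.

The chain-level numerics (``forward_log_partition``, ``viterbi_decode``,
``sequence_logscore``) are plain functions over a state-score matrix ``S``
(L × n_labels) and a transition matrix ``T`` (n_labels × n_labels), so the
scoring path can be checked directly against exhaustive enumeration.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import SVC

from .corpus import BIO_LABELS, LABEL_RANK, Sentence
from .features import FeatureConfig, pos_tag, sentence_features, token_features

TrainingPair = tuple[Sentence, Sequence[str]]
SemTags = Sequence[Sequence[str]] | None


class SequenceLabeler(Protocol):
    """Common contract: fit on (sentence, labels) pairs, predict per token."""

    def fit(self, training: Sequence[TrainingPair],
            semantic_tags: SemTags = None) -> "SequenceLabeler": ...

    def predict(self, sentence: Sentence,
                semantic_tags: Sequence[str] | None = None) -> list[str]: ...


def _check_training(training: Sequence[TrainingPair], semantic_tags: SemTags) -> None:
    if not training:
        raise ValueError("empty training set")
    for si, (sent, labels) in enumerate(training):
        if len(labels) != len(sent):
            raise ValueError(f"labels misaligned at training sentence {si}")
        if semantic_tags is not None and len(semantic_tags[si]) != len(sent):
            raise ValueError(f"semantic tags misaligned at training sentence {si}")


def _sorted_label_list(labels: set[str]) -> list[str]:
    return sorted(labels, key=lambda lab: LABEL_RANK[lab])


def _csr32(X):
    # libsvm only accepts 32-bit sparse indices
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return X


# ---------------------------------------------------------------------------
# SVM


@dataclass
class SVMConfig:
    """Kernel and decoding parameters of the SVM tagger."""

    kernel_degree: int = 2
    c_value: float = 1.0
    window: int = 2

    def __post_init__(self) -> None:
        if self.kernel_degree < 1:
            raise ValueError("kernel degree must be >= 1")
        if self.c_value <= 0:
            raise ValueError("c must be > 0")


class SVMTagger:
    """One-vs-one polynomial-kernel SVM with greedy history decoding."""

    def __init__(self, cfg: SVMConfig | None = None,
                 fcfg: FeatureConfig | None = None) -> None:
        self.cfg = cfg or SVMConfig()
        fcfg = fcfg or FeatureConfig()
        if fcfg.window != self.cfg.window:
            fcfg = FeatureConfig(**{**fcfg.to_dict(), "window": self.cfg.window})
        self.fcfg = fcfg
        self._svc: SVC | None = None
        self._vec: DictVectorizer | None = None
        self.classes_: list[str] = []

    @property
    def n_pairwise_(self) -> int:
        """Number of pairwise binary classifiers, n(n−1)/2."""
        self._require_fitted()
        n = len(self.classes_)
        return n * (n - 1) // 2

    def _require_fitted(self) -> None:
        if not self.classes_:
            raise RuntimeError("SVMTagger is not fitted")

    def fit(self, training: Sequence[TrainingPair],
            semantic_tags: SemTags = None) -> "SVMTagger":
        _check_training(training, semantic_tags)
        dicts: list[dict] = []
        y: list[str] = []
        for si, (sent, labels) in enumerate(training):
            tags = semantic_tags[si] if semantic_tags is not None else None
            # gold history labels at training time
            dicts.extend(sentence_features(sent, tags, labels, self.fcfg))
            y.extend(labels)
        self._vec = DictVectorizer()
        X = _csr32(self._vec.fit_transform(dicts))
        self.classes_ = _sorted_label_list(set(y))
        if len(self.classes_) > 1:
            idx = {lab: k for k, lab in enumerate(self.classes_)}
            self._svc = SVC(
                C=self.cfg.c_value,
                kernel="poly",
                degree=self.cfg.kernel_degree,
                gamma=1.0,
                coef0=1.0,
                decision_function_shape="ovo",
                cache_size=500,
            )
            self._svc.fit(X, np.array([idx[lab] for lab in y]))
        return self

    def _pairwise_votes(self, X) -> np.ndarray:
        """Vote counts per class from the ovo decision values.

        Columns of the ovo decision function are ordered (0,1), (0,2), …;
        a positive value is a vote for the lower-indexed class.
        """
        df = self._svc.decision_function(X)
        if df.ndim == 1:
            df = df[:, None]
        n = len(self.classes_)
        votes = np.zeros((df.shape[0], n))
        col = 0
        for a in range(n):
            for b in range(a + 1, n):
                pos = df[:, col] > 0
                votes[pos, a] += 1
                votes[~pos, b] += 1
                col += 1
        return votes

    def _decide(self, votes: np.ndarray) -> list[str]:
        # max votes; ties broken by the fixed label order (classes_ is
        # already sorted that way, and argmax takes the first maximum)
        return [self.classes_[int(k)] for k in np.argmax(votes, axis=1)]

    def predict(self, sentence: Sentence,
                semantic_tags: Sequence[str] | None = None) -> list[str]:
        self._require_fitted()
        if len(sentence) == 0:
            return []
        if len(self.classes_) == 1:
            return [self.classes_[0]] * len(sentence)
        pos = pos_tag(sentence) if self.fcfg.use_pos else None
        if not self.fcfg.use_history:
            dicts = [
                token_features(sentence, i, semantic_tags, None, self.fcfg, _pos=pos)
                for i in range(len(sentence))
            ]
            return self._decide(
                self._pairwise_votes(_csr32(self._vec.transform(dicts)))
            )
        out: list[str] = []
        for i in range(len(sentence)):
            fd = token_features(sentence, i, semantic_tags, out, self.fcfg, _pos=pos)
            out.extend(
                self._decide(self._pairwise_votes(_csr32(self._vec.transform([fd]))))
            )
        return out


# ---------------------------------------------------------------------------
# Linear-chain CRF numerics (state scores S: L×K, transitions T: K×K)


def sequence_logscore(S: np.ndarray, T: np.ndarray, y: Sequence[int]) -> float:
    """Unnormalized log score Σ_i S[i, y_i] + Σ_i T[y_{i-1}, y_i]."""
    y = np.asarray(y)
    score = float(S[np.arange(len(y)), y].sum())
    if len(y) > 1:
        score += float(T[y[:-1], y[1:]].sum())
    return score


def forward_log_partition(S: np.ndarray, T: np.ndarray) -> float:
    """log Z(x) by the forward algorithm (log-space)."""
    alpha = S[0].astype(float)
    for t in range(1, S.shape[0]):
        alpha = logsumexp(alpha[:, None] + T, axis=0) + S[t]
    return float(logsumexp(alpha))


def viterbi_decode(S: np.ndarray, T: np.ndarray) -> list[int]:
    """Highest-scoring label index sequence; ties resolve to the lowest
    index (argmax takes the first maximum), which is the fixed label order
    when labels are sorted canonically."""
    L, K = S.shape
    delta = S[0].astype(float)
    back = np.zeros((L, K), dtype=np.int64)
    for t in range(1, L):
        cand = delta[:, None] + T  # K_prev × K_cur
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + S[t]
    path = [int(np.argmax(delta))]
    for t in range(L - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path


class CRFTagger:
    """Linear-chain CRF over token features × label, with label-bigram
    transition features (when ``fcfg.use_bigram``)."""

    def __init__(self, fcfg: FeatureConfig | None = None, l2: float = 1.0,
                 max_iter: int = 200) -> None:
        self.fcfg = fcfg or FeatureConfig()
        self.l2 = l2
        self.max_iter = max_iter
        self.W: np.ndarray | None = None  # (n_feats, K) state weights
        self.T: np.ndarray | None = None  # (K, K) transition weights
        self.feature_index: dict[str, int] = {}
        self.classes_: list[str] = []

    # -- featurization -----------------------------------------------------

    def _featurize(self, sent: Sentence,
                   tags: Sequence[str] | None) -> list[dict[str, float]]:
        # the CRF never uses the history family (bigram transitions play
        # that role), so prev_labels stays None
        return sentence_features(sent, tags, None, self.fcfg)

    def _feat_ids(self, dicts: list[dict[str, float]],
                  grow: bool) -> list[np.ndarray]:
        out = []
        for d in dicts:
            ids = []
            for name in d:
                k = self.feature_index.get(name)
                if k is None and grow:
                    k = len(self.feature_index)
                    self.feature_index[name] = k
                if k is not None:
                    ids.append(k)
            out.append(np.asarray(sorted(ids), dtype=np.int64))
        return out

    def _state_scores(self, feat_ids: Sequence[np.ndarray]) -> np.ndarray:
        S = np.zeros((len(feat_ids), len(self.classes_)))
        for i, ids in enumerate(feat_ids):
            if len(ids):
                S[i] = self.W[ids].sum(axis=0)
        return S

    # -- training ----------------------------------------------------------

    def fit(self, training: Sequence[TrainingPair],
            semantic_tags: SemTags = None) -> "CRFTagger":
        _check_training(training, semantic_tags)
        self.feature_index = {}
        all_ids: list[list[np.ndarray]] = []
        all_gold: list[np.ndarray] = []
        labels_seen: set[str] = set()
        for si, (sent, labels) in enumerate(training):
            if len(sent) == 0:
                continue
            tags = semantic_tags[si] if semantic_tags is not None else None
            all_ids.append(self._feat_ids(self._featurize(sent, tags), grow=True))
            all_gold.append(labels)
            labels_seen.update(labels)
        self.classes_ = _sorted_label_list(labels_seen)
        lab_idx = {lab: k for k, lab in enumerate(self.classes_)}
        golds = [np.array([lab_idx[l] for l in g], dtype=np.int64) for g in all_gold]

        K = len(self.classes_)
        F = len(self.feature_index)
        n_pos = sum(len(g) for g in golds)

        # flat layout: every (sentence, position) gets a global row
        feat_flat = np.concatenate([ids for s in all_ids for ids in s]) \
            if n_pos else np.zeros(0, dtype=np.int64)
        counts = np.array([len(ids) for s in all_ids for ids in s], dtype=np.int64)
        feat_row = np.repeat(np.arange(n_pos), counts)
        gold_flat = np.concatenate(golds)

        # group sentences by length for batched forward-backward
        lengths = np.array([len(g) for g in golds])
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        groups: dict[int, list[int]] = {}
        for si, L in enumerate(lengths):
            groups.setdefault(int(L), []).append(si)
        group_rows = {
            L: np.stack([np.arange(starts[si], starts[si] + L) for si in sids])
            for L, sids in groups.items()
        }  # (B, L) global row ids per length group

        use_T = self.fcfg.use_bigram
        n_params = F * K + (K * K if use_T else 0)

        def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            W = theta[: F * K].reshape(F, K)
            T = theta[F * K:].reshape(K, K) if use_T else np.zeros((K, K))
            return W, T

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            W, T = unpack(theta)
            # state scores for every global row
            S_all = np.zeros((n_pos, K))
            np.add.at(S_all, feat_row, W[feat_flat])
            nll = 0.0
            M_all = np.zeros((n_pos, K))  # state marginals
            gradT = np.zeros((K, K))
            for L, rows in group_rows.items():
                S = S_all[rows.ravel()].reshape(rows.shape[0], L, K)
                B = rows.shape[0]
                alphas = np.zeros((L, B, K))
                alphas[0] = S[:, 0]
                for t in range(1, L):
                    alphas[t] = (
                        logsumexp(alphas[t - 1][:, :, None] + T[None], axis=1)
                        + S[:, t]
                    )
                betas = np.zeros((L, B, K))
                for t in range(L - 2, -1, -1):
                    betas[t] = logsumexp(
                        T[None] + (S[:, t + 1] + betas[t + 1])[:, None, :], axis=2
                    )
                logZ = logsumexp(alphas[-1], axis=1)  # (B,)
                nll += float(logZ.sum())
                for t in range(L):
                    M_all[rows[:, t]] = np.exp(
                        alphas[t] + betas[t] - logZ[:, None]
                    )
                if L > 1:
                    for t in range(1, L):
                        pair = np.exp(
                            alphas[t - 1][:, :, None]
                            + T[None]
                            + (S[:, t] + betas[t])[:, None, :]
                            - logZ[:, None, None]
                        )
                        gradT += pair.sum(axis=0)
            # subtract gold path score / add gold counts
            nll -= float(S_all[np.arange(n_pos), gold_flat].sum())
            M_all[np.arange(n_pos), gold_flat] -= 1.0
            gradW = np.zeros((F, K))
            np.add.at(gradW, feat_flat, M_all[feat_row])
            if use_T:
                prev_mask = np.ones(n_pos, dtype=bool)
                prev_mask[starts] = False  # no transition into position 0
                # gold transition counts
                trans_counts = np.zeros((K, K))
                np.add.at(trans_counts, (gold_flat[np.where(prev_mask)[0] - 1],
                                         gold_flat[prev_mask]), 1.0)
                nll -= float((T * trans_counts).sum())
                gradT -= trans_counts
            grad = np.concatenate(
                [gradW.ravel()] + ([gradT.ravel()] if use_T else [])
            )
            nll += 0.5 * self.l2 * float(theta @ theta)
            grad += self.l2 * theta
            return nll, grad

        theta0 = np.zeros(n_params)
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter})
        self.W, self.T = unpack(res.x)
        return self

    # -- inference ---------------------------------------------------------

    def _require_fitted(self) -> None:
        if self.W is None:
            raise RuntimeError("CRFTagger is not fitted")

    def _scores_for(self, sentence: Sentence,
                    semantic_tags: Sequence[str] | None) -> np.ndarray:
        dicts = self._featurize(sentence, semantic_tags)
        return self._state_scores(self._feat_ids(dicts, grow=False))

    def predict(self, sentence: Sentence,
                semantic_tags: Sequence[str] | None = None) -> list[str]:
        self._require_fitted()
        if len(sentence) == 0:
            return []
        S = self._scores_for(sentence, semantic_tags)
        return [self.classes_[k] for k in viterbi_decode(S, self.T)]

    def sequence_probability(self, sentence: Sentence, labels: Sequence[str],
                             semantic_tags: Sequence[str] | None = None) -> float:
        """P(y|x) under the fitted chain (forward-algorithm normalizer)."""
        self._require_fitted()
        if len(labels) != len(sentence):
            raise ValueError("labels not aligned to sentence")
        if len(sentence) == 0:
            return 1.0
        try:
            y = [self.classes_.index(lab) for lab in labels]
        except ValueError:
            return 0.0  # label never seen in training has zero mass
        S = self._scores_for(sentence, semantic_tags)
        return float(np.exp(
            sequence_logscore(S, self.T, y) - forward_log_partition(S, self.T)
        ))


def enumerate_sequence_scores(S: np.ndarray, T: np.ndarray):
    """All (label sequence, log score) pairs by brute force — test oracle."""
    L, K = S.shape
    for y in itertools.product(range(K), repeat=L):
        yield y, sequence_logscore(S, T, y)


# Functional wrappers matching the operation-style API ----------------------


def svm_fit(training: Sequence[TrainingPair], semantic_tags: SemTags = None,
            cfg: SVMConfig | None = None,
            fcfg: FeatureConfig | None = None) -> SVMTagger:
    return SVMTagger(cfg, fcfg).fit(training, semantic_tags)


def svm_predict(model: SVMTagger, sentence: Sentence,
                semantic_tags: Sequence[str] | None = None) -> list[str]:
    return model.predict(sentence, semantic_tags)


def crf_fit(training: Sequence[TrainingPair], semantic_tags: SemTags = None,
            fcfg: FeatureConfig | None = None, **kw) -> CRFTagger:
    return CRFTagger(fcfg, **kw).fit(training, semantic_tags)


def crf_predict(model: CRFTagger, sentence: Sentence,
                semantic_tags: Sequence[str] | None = None) -> list[str]:
    return model.predict(sentence, semantic_tags)


def sequence_probability(model: CRFTagger, sentence: Sentence,
                         labels: Sequence[str],
                         semantic_tags: Sequence[str] | None = None) -> float:
    return model.sequence_probability(sentence, labels, semantic_tags)
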