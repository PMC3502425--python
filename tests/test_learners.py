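import itertools

import numpy as np
import pytest

from medner.corpus import BIO_LABELS
from medner.features import FeatureConfig, token_features
from medner.learners import (
    CRFTagger,
    SVMConfig,
    SVMTagger,
    enumerate_sequence_scores,
    forward_log_partition,
    sequence_logscore,
    viterbi_decode,
)

from conftest import make_sentence

SIMPLE_FCFG = FeatureConfig(use_pos=False, use_morph=False, use_ortho=False,
                            use_semantic=False, window=1)


def toy_corpus(n=40, seed=0):
    """Separable corpus: 'lasix' is always B-m, 'mg' ends a dosage, etc."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        words, labels = ["give"], ["O"]
        words += ["lasix"]
        labels += ["B-m"]
        if rng.random() < 0.7:
            words += ["20", "mg"]
            labels += ["B-do", "I-do"]
        if rng.random() < 0.5:
            words += ["daily"]
            labels += ["B-f"]
        pairs.append((make_sentence(words), labels))
    return pairs


class TestSVM:
    def test_pairwise_count_all_thirteen_labels(self):
        # one sentence carrying every label: n(n-1)/2 = 78 for n = 13
        words = [f"w{i}" for i in range(13)]
        labels = list(BIO_LABELS)
        svm = SVMTagger(fcfg=SIMPLE_FCFG).fit(
            [(make_sentence(words), labels)] * 3
        )
        assert len(svm.classes_) == 13
        assert svm.n_pairwise_ == 78

    def test_pairwise_count_two_labels(self):
        pairs = [(make_sentence(["a", "lasix"]), ["O", "B-m"])] * 3
        svm = SVMTagger(fcfg=SIMPLE_FCFG).fit(pairs)
        assert svm.n_pairwise_ == 1

    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            SVMTagger().fit([])

    def test_separable_corpus_recovery(self):
        svm = SVMTagger(fcfg=SIMPLE_FCFG).fit(toy_corpus())
        held_out = make_sentence(["give", "lasix", "20", "mg", "daily"])
        assert svm.predict(held_out) == ["O", "B-m", "B-do", "I-do", "B-f"]

    def test_single_token_sentence(self):
        svm = SVMTagger(fcfg=SIMPLE_FCFG).fit(toy_corpus())
        assert len(svm.predict(make_sentence(["lasix"]))) == 1

    def test_predict_deterministic(self):
        svm = SVMTagger(fcfg=SIMPLE_FCFG).fit(toy_corpus())
        s = make_sentence(["give", "lasix", "daily"])
        assert svm.predict(s) == svm.predict(s)

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            SVMTagger().predict(make_sentence(["a"]))

    def test_votes_equal_bruteforce_pairwise_count(self):
        # three labels -> three pairwise classifiers; re-count votes by hand
        svm = SVMTagger(fcfg=SIMPLE_FCFG).fit(toy_corpus())
        sent = make_sentence(["give", "lasix", "daily"])
        feats = [
            token_features(sent, i, None, ["O"] * 3, svm.fcfg)
            for i in range(3)
        ]
        X = svm._vec.transform(feats).tocsr()
        X.indices = X.indices.astype(np.int32)
        X.indptr = X.indptr.astype(np.int32)
        df = svm._svc.decision_function(X)
        n = len(svm.classes_)
        votes = np.zeros((3, n))
        col = 0
        for a, b in itertools.combinations(range(n), 2):
            for row in range(3):
                if df[row, col] > 0:
                    votes[row, a] += 1
                else:
                    votes[row, b] += 1
            col += 1
        assert np.array_equal(votes, svm._pairwise_votes(X))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SVMConfig(kernel_degree=0)
        with pytest.raises(ValueError):
            SVMConfig(c_value=0)


class TestCRFNumerics:
    def test_normalization_and_viterbi_against_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            L = int(rng.integers(1, 4))
            K = int(rng.integers(2, 6))
            S = rng.normal(scale=2.0, size=(L, K))
            T = rng.normal(scale=2.0, size=(K, K))
            logZ = forward_log_partition(S, T)
            total = sum(
                np.exp(sc - logZ) for _, sc in enumerate_sequence_scores(S, T)
            )
            assert abs(total - 1.0) < 1e-8
            best_y, best_sc = max(enumerate_sequence_scores(S, T),
                                  key=lambda t: t[1])
            vit = viterbi_decode(S, T)
            assert sequence_logscore(S, T, vit) == pytest.approx(best_sc)

    def test_single_position_two_labels_closed_form(self):
        S = np.array([[1.0, 3.0]])
        T = np.zeros((2, 2))
        assert viterbi_decode(S, T) == [1]
        p = np.exp(3.0) / (np.exp(1.0) + np.exp(3.0))
        assert np.exp(
            sequence_logscore(S, T, [1]) - forward_log_partition(S, T)
        ) == pytest.approx(p)

    def test_zero_weights_uniform_distribution(self):
        K, L = 4, 3
        S = np.zeros((L, K))
        T = np.zeros((K, K))
        logZ = forward_log_partition(S, T)
        assert np.exp(0.0 - logZ) == pytest.approx(K ** -L)


class TestCRFTagger:
    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            CRFTagger().fit([])

    def test_separable_corpus_recovery(self):
        crf = CRFTagger(SIMPLE_FCFG).fit(toy_corpus())
        held_out = make_sentence(["give", "lasix", "20", "mg", "daily"])
        assert crf.predict(held_out) == ["O", "B-m", "B-do", "I-do", "B-f"]

    def test_sequence_probabilities_sum_to_one(self):
        crf = CRFTagger(SIMPLE_FCFG).fit(toy_corpus(n=10))
        sent = make_sentence(["give", "lasix"])
        total = sum(
            crf.sequence_probability(sent, list(y))
            for y in itertools.product(crf.classes_, repeat=2)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_misaligned_labels_raise(self):
        crf = CRFTagger(SIMPLE_FCFG).fit(toy_corpus(n=5))
        with pytest.raises(ValueError):
            crf.sequence_probability(make_sentence(["a", "b"]), ["O"])

    def test_predict_label_per_token_and_known_labels(self):
        crf = CRFTagger(SIMPLE_FCFG).fit(toy_corpus(n=10))
        for words in (["lasix"], ["give", "lasix", "mg"], ["novel", "words"]):
            out = crf.predict(make_sentence(words))
            assert len(out) == len(words)
            assert all(lab in BIO_LABELS for lab in out)

    def test_viterbi_is_most_probable_sequence(self):
        crf = CRFTagger(SIMPLE_FCFG).fit(toy_corpus(n=10))
        sent = make_sentence(["lasix", "mg"])
        pred = crf.predict(sent)
        p_pred = crf.sequence_probability(sent, pred)
        for y in itertools.product(crf.classes_, repeat=2):
            assert p_pred >= crf.sequence_probability(sent, list(y)) - 1e-12
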