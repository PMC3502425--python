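import numpy as np
import pytest

from medner.features import (
    FeatureConfig,
    ORTHO_CATEGORIES,
    affixes,
    orthographic_class,
    pos_tag,
    token_features,
)

from conftest import make_sentence


class TestAffixes:
    def test_standard_word(self):
        pre, suf = affixes("Percocet", 3)
        assert pre == ["P", "Pe", "Per"]
        assert suf == ["t", "et", "cet"]

    def test_word_shorter_than_max(self):
        pre, suf = affixes("at", 3)
        assert pre == ["a", "at"]
        assert suf == ["t", "at"]

    def test_empty_word_raises(self):
        with pytest.raises(ValueError):
            affixes("", 3)

    def test_affix_property_random_words(self):
        rng = np.random.default_rng(0)
        alphabet = "abcdefghij"
        for _ in range(200):
            n = int(rng.integers(1, 12))
            w = "".join(alphabet[int(i)] for i in rng.integers(0, 10, size=n))
            max_len = int(rng.integers(1, 6))
            pre, suf = affixes(w, max_len)
            k = min(max_len, len(w))
            assert len(pre) == len(suf) == k
            assert all(w.startswith(p) for p in pre)
            assert all(w.endswith(s) for s in suf)


class TestOrthography:
    def test_twenty_one_categories(self):
        assert len(ORTHO_CATEGORIES) == 21
        assert len(set(ORTHO_CATEGORIES)) == 21

    @pytest.mark.parametrize(
        "word,expected",
        [
            ("100", "ALL_DIGITS"),
            ("5", "SINGLE_DIGIT"),
            ("40", "DOUBLE_DIGIT"),
            ("0.5", "REAL_NUMBER"),
            ("0.5%", "PERCENT"),
            ("1-2", "RANGE"),
            ("1/2", "DIGIT_SLASH"),
            ("x10", "ALPHA_DIGIT"),
            ("10mg", "DIGIT_ALPHA"),
            ("p.o.", "DOTTED_ABBREV"),
            ("TYLENOL", "ALL_CAPS"),
            ("Percocet", "INIT_CAP"),
            ("tablets", "ALL_LOWER"),
            ("mEq", "MIXED_CASE"),
            ("10-day", "HYPHENATED"),
            ("mg/dl", "SLASH_WORD"),
            ("..", "PUNCT_ONLY"),
            ("(ACETAMINOPHEN)", "HAS_PAREN"),
            ("prn,", "ENDS_COMMA"),
            ("daily.", "ENDS_PERIOD"),
        ],
    )
    def test_category_examples(self, word, expected):
        assert orthographic_class(word) == expected

    def test_total_and_single_valued_on_arbitrary_tokens(self):
        rng = np.random.default_rng(1)
        chars = "aZ0.%-/(),!#"
        for _ in range(500):
            n = int(rng.integers(1, 8))
            w = "".join(chars[int(i)] for i in rng.integers(0, len(chars), n))
            assert orthographic_class(w) in ORTHO_CATEGORIES


class TestPosTagger:
    def test_fallback_rules_on_prescription_tokens(self):
        assert pos_tag(["Percocet", "1-2", "Tablets"]) == ["NN", "CD", "NNS"]

    def test_empty_sentence(self):
        assert pos_tag([]) == []

    def test_output_length_matches_input(self):
        rng = np.random.default_rng(2)
        vocab = ["Lasix", "20", "mg", "daily", "for", "edema.", "p.o.", "(x)"]
        for _ in range(50):
            words = [vocab[int(i)] for i in rng.integers(0, len(vocab),
                                                         int(rng.integers(1, 9)))]
            assert len(pos_tag(words)) == len(words)

    def test_failing_backend_is_reported(self):
        def broken(words):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="backend"):
            pos_tag(make_sentence(["a"]), backend=broken)


def _expected_count(sent, i, cfg, has_sem, has_hist):
    total = 0
    for d in range(-cfg.window, cfg.window + 1):
        j = i + d
        if j < 0 or j >= len(sent):
            total += 1  # boundary marker
            continue
        w = sent.tokens[j].text
        total += cfg.use_word + cfg.use_pos + cfg.use_ortho
        total += (2 * min(cfg.affix_len, len(w))) if cfg.use_morph else 0
        total += 1 if (cfg.use_semantic and has_sem) else 0
    if cfg.use_history and has_hist:
        total += 1
    return total


class TestTokenFeatures:
    def test_window_features_at_sentence_start(self, worked_sentence):
        cfg = FeatureConfig()
        feats = token_features(worked_sentence, 0, None, [], cfg)
        assert "w[+0]=Percocet" in feats
        assert "w[+1]=1-2" in feats
        assert "w[+2]=Tablets" in feats
        assert "bnd[-1]=<S>" in feats and "bnd[-2]=<S>" in feats
        assert "hist=<BOS>" in feats

    def test_minimal_config_single_feature(self, worked_sentence):
        cfg = FeatureConfig(use_pos=False, use_morph=False, use_ortho=False,
                            use_semantic=False, use_history=False, window=0)
        feats = token_features(worked_sentence, 2, cfg=cfg)
        assert feats == {"w[+0]=Tablets": 1.0}

    def test_out_of_range_position_raises(self, worked_sentence):
        with pytest.raises(IndexError):
            token_features(worked_sentence, 7)

    def test_feature_count_matches_closed_form(self):
        rng = np.random.default_rng(3)
        vocab = ["Lasix", "20", "mg", "p.o.", "daily", "x10", "prn,"]
        for _ in range(100):
            n = int(rng.integers(1, 8))
            sent = make_sentence([vocab[int(k)] for k in
                                  rng.integers(0, len(vocab), n)])
            cfg = FeatureConfig(
                use_word=True,
                use_pos=bool(rng.integers(2)),
                use_morph=bool(rng.integers(2)),
                use_ortho=bool(rng.integers(2)),
                use_semantic=bool(rng.integers(2)),
                use_history=bool(rng.integers(2)),
                window=int(rng.integers(0, 3)),
            )
            has_sem = bool(rng.integers(2))
            sem = ["m"] * n if has_sem else None
            i = int(rng.integers(0, n))
            feats = token_features(sent, i, sem, ["O"] * n, cfg)
            assert len(feats) == _expected_count(sent, i, cfg, has_sem, True)

    def test_determinism(self, worked_sentence):
        a = token_features(worked_sentence, 3, ["O"] * 7, ["B-m"] * 7)
        b = token_features(worked_sentence, 3, ["O"] * 7, ["B-m"] * 7)
        assert a == b

    def test_ablation_monotonicity(self, worked_sentence):
        small = FeatureConfig(use_pos=False, use_morph=False, use_ortho=False,
                              use_semantic=False, use_history=False)
        big = FeatureConfig()
        f_small = token_features(worked_sentence, 2, ["m"] * 7, ["O"] * 7, small)
        f_big = token_features(worked_sentence, 2, ["m"] * 7, ["O"] * 7, big)
        assert set(f_small) <= set(f_big)
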