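import numpy as np
import pytest

from medner.corpus import (
    AnnotationParseError,
    BIO_LABELS,
    EntityMention,
    FIELD_CODES,
    Sentence,
    Token,
    decode_bio,
    encode_bio,
    parse_annotation_line,
    tokenize,
    write_annotation_line,
)

from conftest import make_sentence

EXAMPLE_ANN = (
    'm="percocet" 10:0 10:0||do="1-2 tablets" 10:1 10:2||mo="p.o." 10:3 10:3'
    '||f="q 4 prn," 10:4 10:6||du="nm"||r="nm"||ln="list"'
)


class TestLabelScheme:
    def test_six_fields_thirteen_labels(self):
        assert FIELD_CODES == ("m", "do", "mo", "f", "du", "r")
        assert len(BIO_LABELS) == 13
        assert len(set(BIO_LABELS)) == 13
        assert BIO_LABELS[-1] == "O"
        assert {f"B-{c}" for c in FIELD_CODES} <= set(BIO_LABELS)
        assert {f"I-{c}" for c in FIELD_CODES} <= set(BIO_LABELS)


class TestTokenize:
    def test_prescription_line_tokens(self):
        doc = tokenize("Percocet 1-2 Tablets p.o. Q 4 prn,")
        assert [t.text for s in doc.sentences for t in s.tokens] == [
            "Percocet", "1-2", "Tablets", "p.o.", "Q", "4", "prn,",
        ]
        # dotted abbreviation must not split the sentence
        assert len(doc.sentences) == 1

    def test_empty_note(self):
        doc = tokenize("")
        assert doc.sentences == []

    def test_blank_line_splits_sentences(self):
        doc = tokenize("Lasix 20 mg\n\nTylenol prn")
        assert len(doc.sentences) == 2
        assert doc.sentences[1].tokens[0].position == (3, 0)

    def test_period_then_uppercase_splits(self):
        doc = tokenize("Take one daily. Follow up soon")
        assert [len(s) for s in doc.sentences] == [3, 3]

    def test_positions_match_bruteforce_split(self):
        raw = "Lasix 20 mg p.o.\n\nTylenol 650 mg\nprn fever."
        doc = tokenize(raw)
        expected = []
        for li, line in enumerate(raw.split("\n"), start=1):
            for oi, w in enumerate(line.split()):
                expected.append((w, li, oi))
        got = [(t.text, t.line, t.offset) for s in doc.sentences for t in s.tokens]
        assert got == expected


class TestAnnotationDialect:
    def test_parse_example_line(self):
        al = parse_annotation_line(EXAMPLE_ANN)
        assert al.style == "list"
        assert [(m.field, m.start, m.end) for m in al.mentions] == [
            ("m", (10, 0), (10, 0)),
            ("do", (10, 1), (10, 2)),
            ("mo", (10, 3), (10, 3)),
            ("f", (10, 4), (10, 6)),
        ]

    def test_all_absent_fields(self):
        line = '||'.join(f'{c}="nm"' for c in FIELD_CODES) + '||ln="narrative"'
        assert parse_annotation_line(line).mentions == []
        assert write_annotation_line([], "narrative") == line

    @pytest.mark.parametrize(
        "bad",
        [
            'q="drug" 1:0 1:0||ln="list"',  # unknown field code
            'm="drug" 1:x 1:0||ln="list"',  # malformed offset
            'm="drug"||ln="list"',  # present field without a span
        ],
    )
    def test_malformed_line_raises_with_position(self, bad):
        with pytest.raises(AnnotationParseError):
            parse_annotation_line(bad)

    def test_write_is_inverse_of_parse_example(self):
        al = parse_annotation_line(EXAMPLE_ANN)
        assert write_annotation_line(al.mentions, al.style) == EXAMPLE_ANN

    def test_roundtrip_random_mention_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            mentions = []
            used = set()
            for code in FIELD_CODES:
                if rng.random() < 0.5:
                    continue
                line = int(rng.integers(1, 50))
                start = int(rng.integers(0, 20))
                length = int(rng.integers(1, 4))
                span = {(line, start + k) for k in range(length)}
                if span & used:
                    continue
                used |= span
                words = [
                    "w" + str(int(rng.integers(0, 100))) for _ in range(length)
                ]
                mentions.append(
                    EntityMention(code, (line, start),
                                  (line, start + length - 1), " ".join(words))
                )
            out = write_annotation_line(mentions, "list")
            back = parse_annotation_line(out)
            assert sorted(
                (m.field, m.start, m.end, m.text) for m in back.mentions
            ) == sorted((m.field, m.start, m.end, m.text) for m in mentions)


class TestBIO:
    def test_encode_worked_example(self, worked_sentence, worked_mentions,
                                   worked_labels):
        assert encode_bio(worked_sentence, worked_mentions) == worked_labels

    def test_encode_no_mentions_all_outside(self, worked_sentence):
        assert encode_bio(worked_sentence, []) == ["O"] * 7

    def test_encode_overlap_raises(self, worked_sentence):
        overlapping = [
            EntityMention("m", (10, 0), (10, 1), "Percocet 1-2"),
            EntityMention("do", (10, 1), (10, 2), "1-2 Tablets"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            encode_bio(worked_sentence, overlapping)

    def test_decode_worked_example(self, worked_sentence, worked_labels):
        mentions = decode_bio(worked_sentence, worked_labels)
        assert [(m.field, m.text) for m in mentions] == [
            ("m", "Percocet"),
            ("do", "1-2 Tablets"),
            ("mo", "p.o."),
            ("f", "Q 4 prn,"),
        ]

    def test_decode_all_outside(self, worked_sentence):
        assert decode_bio(worked_sentence, ["O"] * 7) == []

    def test_orphan_inside_label_starts_mention(self):
        sent = make_sentence(["take", "ten", "days"])
        mentions = decode_bio(sent, ["O", "I-du", "I-du"])
        assert len(mentions) == 1
        assert mentions[0].field == "du"
        assert (mentions[0].start, mentions[0].end) == ((1, 1), (1, 2))

    def test_decode_matches_bruteforce_run_finder(self):
        rng = np.random.default_rng(7)
        labels_pool = list(BIO_LABELS)
        for _ in range(200):
            n = int(rng.integers(1, 12))
            sent = make_sentence([f"w{i}" for i in range(n)])
            labs = [labels_pool[int(i)] for i in rng.integers(0, 13, size=n)]
            got = {(m.field, m.start[1], m.end[1]) for m in decode_bio(sent, labs)}
            # brute force: every maximal run starting at B-x or orphan I-x
            expected = set()
            i = 0
            while i < n:
                if labs[i] == "O":
                    i += 1
                    continue
                code = labs[i].split("-")[1]
                j = i + 1
                while j < n and labs[j] == f"I-{code}":
                    j += 1
                expected.add((code, i, j - 1))
                i = j
            assert got == expected

    def test_label_sequence_length_always_matches(self):
        sent = make_sentence(["a", "b"])
        with pytest.raises(ValueError):
            decode_bio(sent, ["O"])
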