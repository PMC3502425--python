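import pytest

from medner.corpus import EntityMention, Sentence, Token


@pytest.fixture
def worked_sentence() -> Sentence:
    """The worked prescription-line example: one list-style sentence with a
    medication, dosage, mode and frequency field."""
    words = ["Percocet", "1-2", "Tablets", "p.o.", "Q", "4", "prn,"]
    return Sentence([Token(w, 10, i) for i, w in enumerate(words)], "note10")


@pytest.fixture
def worked_mentions() -> list[EntityMention]:
    return [
        EntityMention("m", (10, 0), (10, 0), "Percocet", "note10"),
        EntityMention("do", (10, 1), (10, 2), "1-2 Tablets", "note10"),
        EntityMention("mo", (10, 3), (10, 3), "p.o.", "note10"),
        EntityMention("f", (10, 4), (10, 6), "Q 4 prn,", "note10"),
    ]


@pytest.fixture
def worked_labels() -> list[str]:
    return ["B-m", "B-do", "I-do", "B-mo", "B-f", "I-f", "I-f"]


def make_sentence(words, line=1, doc_id="doc") -> Sentence:
    return Sentence([Token(w, line, i) for i, w in enumerate(words)], doc_id)
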