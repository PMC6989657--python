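"""Cleansing, tokenization, segmentation, vocabulary and padding contracts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocnn.preprocessing import (
    PAD_INDEX,
    UNK_INDEX,
    Vocabulary,
    build_vocabulary,
    cleanse,
    index_and_pad_sentences,
    index_and_pad_words,
    segment_sentences,
    tokenize,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("BP:\t120/80 [stable]", "BP 120 80 stable"),
        ("", ""),
        ("a   b", "a b"),
        ("chest pain!", "chest pain!"),
        ("x′y", "x'y"),  # prime glyph normalized to apostrophe
        ("  leading & trailing  ", "leading trailing"),
    ],
)
def test_cleanse_replaces_and_collapses(raw, expected):
    assert cleanse(raw) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("chest pain !", ["chest", "pain", "!"]),
        ("", []),
        ("pain(severe)", ["pain", "(", "severe", ")"]),
        ("a, b.", ["a", ",", "b", "."]),
    ],
)
def test_tokenize_splits_and_emits_punctuation(text, expected):
    assert tokenize(text) == expected


@given(st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126), max_size=80))
@settings(max_examples=50, deadline=None)
def test_tokenize_cleanse_round_trip(text):
    """Rejoining tokens reproduces cleansed text up to punctuation spacing."""
    clean = cleanse(text)
    rejoined = " ".join(tokenize(clean))
    assert rejoined == " ".join(tokenize(rejoined))
    # token characters are conserved (only spacing differs)
    assert rejoined.replace(" ", "") == clean.replace(" ", "")


@pytest.mark.parametrize(
    "text,expected",
    [
        ("a b . c d .", [["a", "b"], ["c", "d"]]),
        ("t1 t2 t3 t4 t5 t6 , t7 .", [["t1", "t2", "t3", "t4", "t5", "t6"], ["t7"]]),
        ("t1 t2 , t3 .", [["t1", "t2", "t3"]]),
        (". . .", []),
        ("tail with no period", [["tail", "with", "no", "period"]]),
    ],
)
def test_segment_sentences_rules(text, expected):
    assert segment_sentences(text) == expected


def test_segmentation_conserves_non_boundary_tokens(small_corpus):
    """Word-level multiset equals the union of sentence-level multisets."""
    for doc in small_corpus.notes[:10]:
        text = " . ".join(" ".join(s) for s in doc) + " ."
        flat = [t for t in tokenize(text) if t not in {".", ","}]
        seg = [t for s in segment_sentences(text) for t in s]
        assert sorted(flat) == sorted(seg)


class TestVocabulary:
    def test_reserved_entries(self):
        vocab = build_vocabulary([["chest", "pain", "chest"]])
        assert vocab.index("unk") == UNK_INDEX
        assert vocab.index("padding") == PAD_INDEX
        assert vocab.index("chest") == 3  # first appearance
        assert vocab.index("pain") == 4
        assert len(vocab) == 4  # 2 real + 2 reserved

    def test_size_counts_reserved(self):
        corpus = [[f"t{i}" for i in range(10)]]
        assert len(build_vocabulary(corpus)) == 12

    def test_case_folding(self):
        assert len(build_vocabulary([["A", "a"]], case_sensitive=False)) == 3
        assert len(build_vocabulary([["A", "a"]], case_sensitive=True)) == 4

    def test_unseen_token_maps_to_unk(self):
        vocab = build_vocabulary([["a"]])
        assert vocab.index("zzz") == UNK_INDEX

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])

    def test_tsv_round_trip(self, tmp_path):
        vocab = build_vocabulary([["a", "b", "c", "a"]])
        path = tmp_path / "vocab.tsv"
        vocab.to_tsv(path)
        back = Vocabulary.from_tsv(path)
        assert back.tokens == vocab.tokens

    def test_reverse_lookup_restores_tokens(self, small_corpus):
        docs = [[t for s in doc for t in s] for doc in small_corpus.notes[:5]]
        vocab = build_vocabulary(docs)
        for doc in docs:
            restored = [vocab.token(vocab.index(t)) for t in doc]
            assert restored == doc


class TestPadding:
    def test_empty_note(self):
        vocab = build_vocabulary([["a"]])
        note = index_and_pad_words([], vocab, 3)
        assert note.indices.tolist() == [PAD_INDEX] * 3
        assert note.true_length == 0

    def test_padding_is_suffix_and_order_preserved(self):
        vocab = build_vocabulary([["a", "b"]])
        note = index_and_pad_words(["b", "a"], vocab, 4)
        assert note.indices.tolist() == [4, 3, PAD_INDEX, PAD_INDEX]
        assert note.true_length == 2

    def test_overlong_rejected_by_default(self):
        vocab = build_vocabulary([["a"]])
        with pytest.raises(ValueError):
            index_and_pad_words(["a", "a"], vocab, 1)

    def test_overlong_truncation_policy(self):
        vocab = build_vocabulary([["a", "b"]])
        with pytest.warns(UserWarning):
            note = index_and_pad_words(["a", "b"], vocab, 1, overflow="truncate")
        assert note.indices.tolist() == [3]

    def test_sentence_padding_two_dimensional(self):
        vocab = build_vocabulary([["a"]])
        snote = index_and_pad_sentences([["a"]], vocab, W_max=2, S_max=2)
        assert snote.indices.tolist() == [[3, PAD_INDEX], [PAD_INDEX, PAD_INDEX]]
        assert snote.sentence_lengths.tolist() == [1, 0]
        assert snote.n_sentences == 1

    def test_sentence_lengths_conserved(self, small_corpus):
        doc = small_corpus.notes[0]
        vocab = build_vocabulary([doc])
        W = max(len(s) for s in doc)
        snote = index_and_pad_sentences(doc, vocab, W_max=W, S_max=len(doc) + 2)
        assert snote.sentence_lengths[: len(doc)].tolist() == [len(s) for s in doc]
        assert (snote.sentence_lengths[len(doc) :] == 0).all()


@given(
    st.lists(
        st.sampled_from(["fever", "cough", "bp", "120", "ward"]), max_size=12
    )
)
@settings(max_examples=40, deadline=None)
def test_index_then_reverse_lookup_is_identity(tokens):
    vocab = build_vocabulary([tokens or ["x"]])
    note = index_and_pad_words(tokens, vocab, 15)
    restored = [vocab.token(int(i)) for i in note.indices[: note.true_length]]
    assert restored == tokens
    assert (note.indices[note.true_length :] == PAD_INDEX).all()
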