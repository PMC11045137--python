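"""Tokenization, date tagging, context detection and ROOC substitution."""

import pytest
from hypothesis import given, settings, strategies as st

from numnote import textprep as tp


@pytest.mark.parametrize("text,expected", [
    ("BUN 24.0 (H)", ["BUN", "24.0", "(H)"]),
    ("creatinine .7 (L)", ["creatinine", ".7", "(L)"]),
    ("", []),
    ("Cl 93.0 (L) 03/04/18 creatinine 5.2 (H)",
     ["Cl", "93.0", "(L)", "03/04/18", "creatinine", "5.2", "(H)"]),
    ("fatigue, dizziness.", ["fatigue", ",", "dizziness", "."]),
    ("1.2.3 stays", ["1.2.3", "stays"]),
    ("03/04/18-BUN 24.0", ["03/04/18-BUN", "24.0"]),
])
def test_tokenize(text, expected):
    assert tp.tokenize(text).tokens == expected


@pytest.mark.parametrize("tokens,expected", [
    (["creatinine", "5.2", "(H)", "03/05/18"],
     ["creatinine", "5.2", "(H)", "_date_"]),
    (["BUN", "24.0"], ["BUN", "24.0"]),
    (["01/02/2020", "x", "03/04/18"], ["_date_", "x", "_date_"]),
    (["03/04/18-BUN"], ["_date_-BUN"]),
])
def test_tag_dates(tokens, expected):
    assert tp.tag_dates(tp.TokenSequence(tokens)).tokens == expected


def test_tag_dates_preserves_length():
    seq = tp.TokenSequence(["a", "01/02/03", "b", "4.5"])
    assert len(tp.tag_dates(seq)) == len(seq)


class TestNumericMentions:
    def test_in_context_number(self):
        seq = tp.TokenSequence(["creatinine", "5.2", "(H)"])
        (m,) = tp.find_numeric_mentions(seq)
        assert (m.position, m.value, m.keyword, m.in_context) == \
            (1, 5.2, "creatinine", True)

    def test_out_of_context_number(self):
        seq = tp.TokenSequence(["Cl", "93.0", "(L)"])
        (m,) = tp.find_numeric_mentions(seq)
        assert m.keyword is None and not m.in_context

    def test_empty_sequence(self):
        assert tp.find_numeric_mentions(tp.TokenSequence([])) == []

    def test_pseudo_number_is_not_a_mention(self):
        seq = tp.TokenSequence(["BUN", "1.2.3"])
        assert tp.find_numeric_mentions(seq) == []

    def test_left_context(self):
        # number one token left of the keyword is in context
        seq = tp.TokenSequence(["24.0", "BUN"])
        (m,) = tp.find_numeric_mentions(seq)
        assert m.in_context and m.keyword == "bun"

    def test_window_bound_right(self):
        seq = tp.TokenSequence(["BUN", "x", "y", "24.0"])
        (m,) = tp.find_numeric_mentions(seq)
        assert not m.in_context  # 3 tokens right of the keyword

    def test_hyphen_fused_keyword(self):
        seq = tp.TokenSequence(["_date_-bun", "24.0", "(H)"])
        (m,) = tp.find_numeric_mentions(seq)
        assert m.in_context and m.keyword == "bun"

    def test_keyword_case_insensitive(self):
        seq = tp.TokenSequence(["Creatinine", "4.7", "(H)"])
        (m,) = tp.find_numeric_mentions(seq)
        assert m.in_context


@pytest.mark.parametrize("tokens,expected", [
    (["Cl", "93.0", "(L)"], ["Cl", "_INUM_", "(L)"]),
    (["heart", "rate", "1500.0"], ["heart", "rate", "_lgnum_"]),
    (["creatinine", "5.2", "(H)"], ["creatinine", "5.2", "(H)"]),
    (["exactly", "1000"], ["exactly", "_INUM_"]),  # tie maps small
])
def test_rooc_transform(tokens, expected):
    seq = tp.TokenSequence(tokens)
    out = tp.rooc_transform(seq, tp.find_numeric_mentions(seq))
    assert out.tokens == expected


_token = st.sampled_from(
    ["BUN", "creatinine", "Cl", "(H)", "(L)", "word", "_date_",
     "24.0", ".7", "93.0", "1500.0", "5.2", "1000", "03/04/18"])
_seqs = st.lists(_token, max_size=12).map(tp.TokenSequence)


@settings(deadline=None, max_examples=200)
@given(_seqs)
def test_rooc_idempotent_and_length_preserving(seq):
    first = tp.rooc_transform(seq, tp.find_numeric_mentions(seq))
    second = tp.rooc_transform(first, tp.find_numeric_mentions(first))
    assert second.tokens == first.tokens
    assert len(first) == len(seq)


@settings(deadline=None, max_examples=200)
@given(_seqs, st.integers(0, 2), st.integers(0, 3))
def test_in_context_matches_brute_force(seq, left, right):
    keywords = ("bun", "creatinine")
    mentions = tp.find_numeric_mentions(seq, keywords, left, right)
    kw_pos = [i for i, t in enumerate(seq.tokens)
              if t.lower() in keywords or
              any(t.lower().endswith("-" + k) for k in keywords)]
    for m in mentions:
        brute = any(k - left <= m.position <= k + right and m.position != k
                    for k in kw_pos)
        assert m.in_context == brute


class TestVocabulary:
    corpus = [tp.TokenSequence(["Cl", "93.0", "(L)", "creatinine", "5.2", "(H)"]),
              tp.TokenSequence(["BUN", "24.0", "(H)", "word"])]

    def test_basic_keeps_numbers(self):
        v = tp.build_vocab(self.corpus, tp.EmbeddingMode.BASIC)
        assert "93.0" in v and "5.2" in v

    def test_rooc_drops_ooc_numbers(self):
        v = tp.build_vocab(self.corpus, tp.EmbeddingMode.ROOC)
        assert "93.0" not in v and tp.INUM_TAG in v and "5.2" in v

    def test_scalenum_drops_all_numbers(self):
        v = tp.build_vocab(self.corpus, tp.EmbeddingMode.SCALENUM)
        assert "5.2" not in v and "24.0" not in v and "93.0" not in v

    def test_pad_id_reserved(self):
        v = tp.build_vocab(self.corpus, tp.EmbeddingMode.BASIC)
        ids = list(v.token_to_id.values())
        assert ids.count(0) == 1 and v.token_to_id["<pad>"] == 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tp.build_vocab([], tp.EmbeddingMode.BASIC)


class TestEncode:
    vocab = tp.build_vocab(
        [tp.TokenSequence(["a", "b", "c"])], tp.EmbeddingMode.BASIC)

    def test_padding(self):
        ids = tp.encode(tp.TokenSequence(["a", "b"]), self.vocab, max_len=10)
        assert len(ids) == 10 and ids[2:] == [0] * 8 and 0 not in ids[:2]

    def test_truncation(self):
        seq = tp.TokenSequence(["a"] * 50)
        assert len(tp.encode(seq, self.vocab, max_len=30)) == 30

    def test_unknown_maps_to_unk(self):
        ids = tp.encode(tp.TokenSequence(["zzz"]), self.vocab, max_len=3)
        assert ids[0] == tp.Vocabulary.UNK_ID

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.sampled_from(["a", "b", "zzz"]), max_size=20),
           st.integers(1, 15))
    def test_length_always_max_len(self, tokens, max_len):
        ids = tp.encode(tp.TokenSequence(tokens), self.vocab, max_len)
        assert len(ids) == max_len
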