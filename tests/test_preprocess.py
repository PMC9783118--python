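"""Tokenization, sentence segmentation, section detection, chunking."""

import pytest
from hypothesis import given, settings, strategies as st

from substex.model import Record
from substex.preprocess import (
    detect_sections,
    segment_and_tokenize,
    shallow_chunk,
)


def _tokens(lex, text):
    (sentence,) = segment_and_tokenize(Record("t", text))
    return sentence.tokens


class TestTokenizer:
    def test_hyphen_compound_stays_single(self, lex):
        texts = [t.text for t in _tokens(lex, "He is an ex-smoker.")]
        assert "ex-smoker" in texts

    def test_sign_prefix_stays_attached(self, lex):
        texts = [t.text for t in _tokens(lex, "-tob, +etho")]
        assert texts == ["-tob", ",", "+etho"]

    def test_spelled_numbers_are_cd(self, lex):
        toks = {t.text: t.pos_tag for t in _tokens(lex, "two to three beers")}
        assert toks["two"] == "CD" and toks["three"] == "CD"
        assert toks["beers"] != "CD"

    @pytest.mark.parametrize("token", ["1-2", "3–4", "1/2", "3/2/05", "1994", "half"])
    def test_numericish_tokens_are_single_cd(self, lex, token):
        match = [t for t in _tokens(lex, f"value {token} here") if t.text == token]
        assert len(match) == 1 and match[0].pos_tag == "CD"

    def test_punctuation_is_not_word(self, lex):
        toks = _tokens(lex, "smoke, alcohol.")
        flags = {t.text: t.is_word for t in toks}
        assert flags[","] is False and flags["smoke"] is True

    def test_offsets_slice_cleanly(self, lex):
        text = "He smokes 1-2 packs per day."
        for t in _tokens(lex, text):
            assert text[t.char_start:t.char_end] == t.text


class TestSegmentation:
    def test_abbreviation_does_not_split(self, lex):
        sentences = segment_and_tokenize(Record("t", "Seen by Dr. Smith today. He smokes."))
        assert len(sentences) == 2
        assert "Dr. Smith" in sentences[0].text_of("Seen by Dr. Smith today. He smokes.")

    def test_newline_splits_list_items(self, lex):
        text = "Tobacco: none\nAlcohol: none\n"
        assert len(segment_and_tokenize(Record("t", text))) == 2

    def test_sentence_spans_ordered_nonoverlapping(self, lex):
        text = "One. Two! Three? Four\nFive."
        sentences = segment_and_tokenize(Record("t", text))
        spans = [(s.char_start, s.char_end) for s in sentences]
        assert spans == sorted(spans)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b <= c


class TestSections:
    def test_all_caps_header(self, lex):
        record = Record("t", "ALLERGIES: penicillin.")
        sections = detect_sections(record, lex)
        assert [s.canonical_name for s in sections] == ["ALLERGIES"]

    def test_known_mixed_case_header(self, lex):
        record = Record(
            "t",
            "Follow up and Instructions: You should continue to take adequate food and drink",
        )
        sections = detect_sections(record, lex)
        assert sections[0].canonical_name == "FOLLOW_UP_INSTRUCTIONS"

    def test_unknown_mixed_case_is_not_header(self, lex):
        record = Record("t", "Some prose: more prose here.")
        sections = detect_sections(record, lex)
        assert [s.canonical_name for s in sections] == ["PREAMBLE"]

    def test_no_headers_yields_preamble(self, lex):
        record = Record("t", "no colon-terminated lines here\nat all")
        sections = detect_sections(record, lex)
        assert len(sections) == 1
        assert sections[0].canonical_name == "PREAMBLE"
        assert (sections[0].char_start, sections[0].char_end) == (0, len(record.text))

    def test_sections_partition_record(self, lex):
        text = "preamble text\nSOCIAL HISTORY: smokes.\nALLERGIES: none.\n"
        record = Record("t", text)
        sections = detect_sections(record, lex)
        assert sections[0].char_start == 0
        assert sections[-1].char_end == len(text)
        for a, b in zip(sections, sections[1:]):
            assert a.char_end == b.char_start

    def test_sentences_inherit_section(self, lex):
        text = "SOCIAL HISTORY: He smokes.\nALLERGIES: penicillin.\n"
        record = Record("t", text)
        sentences = segment_and_tokenize(record, detect_sections(record, lex))
        assert sentences[0].section == "SOCIAL_HISTORY"
        assert sentences[1].section == "ALLERGIES"


class TestChunking:
    def _chunks(self, lex, text):
        (sentence,) = segment_and_tokenize(Record("t", text))
        return sentence, shallow_chunk(sentence)

    def test_noun_run_groups(self, lex):
        sentence, chunks = self._chunks(lex, "drinks orange juice daily")
        groups = [
            [sentence.tokens[i].text for i in range(c.token_span[0], c.token_span[1])]
            for c in chunks
        ]
        assert ["orange", "juice"] in groups
        assert ["drinks"] in groups  # verb stays a singleton

    def test_numeric_range_with_bridges_is_one_chunk(self, lex):
        sentence, chunks = self._chunks(lex, "2 and 1/2 to 3 packs")
        np = max(chunks, key=lambda c: c.token_span[1] - c.token_span[0])
        covered = [sentence.tokens[i].text for i in range(*np.token_span)]
        assert covered == ["2", "and", "1/2", "to", "3", "packs"]

    def test_single_token_sentence(self, lex):
        sentence, chunks = self._chunks(lex, "Smoking.")
        word_chunks = [c for c in chunks if sentence.tokens[c.token_span[0]].is_word]
        assert len(word_chunks) == 1
        assert word_chunks[0].token_span == (0, 1)

    def test_chunks_partition_tokens(self, lex):
        sentence, chunks = self._chunks(
            lex, "He smoked 2 packs per day for 30 years but stopped smoking in 1994."
        )
        covered = sorted(
            i for c in chunks for i in range(c.token_span[0], c.token_span[1])
        )
        assert covered == list(range(len(sentence.tokens)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.text(
        alphabet=st.sampled_from(
            list("abcdefghijklmnop ABC.,!?-+/0123456789\n")
        ),
        max_size=120,
    )
)
def test_tokenization_round_trip_and_determinism(text):
    """Token offsets always slice cleanly, chunks always partition, and
    re-running preprocessing yields identical structures."""
    record = Record("t", text)
    first = segment_and_tokenize(record)
    second = segment_and_tokenize(record)
    assert [s.char_start for s in first] == [s.char_start for s in second]
    for sentence in first:
        for token in sentence.tokens:
            assert text[token.char_start:token.char_end] == token.text
        chunks = shallow_chunk(sentence)
        covered = sorted(i for c in chunks for i in range(*c.token_span))
        assert covered == list(range(len(sentence.tokens)))
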