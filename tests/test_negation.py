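"""Stage 2: extended NegEx rules, window scopes, aggregation, baseline contrast."""

import pytest

from substex.model import Record, Status, Substance
from substex.negation import (
    NegationConfig,
    Polarity,
    PolarityDecision,
    Rule,
    aggregate_polarity,
    polarity_of_mention,
)
from substex.pipeline import run_record
from substex.preprocess import detect_sections, segment_and_tokenize
from substex.relevance import find_mentions

S, A, D = Substance.SMOKING, Substance.ALCOHOL, Substance.DRUG


def _decide(lex, text, keyword, cfg=None):
    record = Record("t", text)
    sections = detect_sections(record, lex)
    sentences = segment_and_tokenize(record, sections)
    mentions = find_mentions(sentences, lex, record.text)
    mention = next(m for m in mentions if m.active and m.keyword == keyword)
    sentence = sentences[mention.sentence_index]
    sentence_mentions = [m for m in mentions if m.sentence_index == mention.sentence_index]
    return polarity_of_mention(
        mention, sentence, sections, lex, cfg or NegationConfig(), sentence_mentions
    )


class TestExtensionRules:
    def test_semantic_negation_words(self, lex):
        d1 = _decide(lex, "She is a non-smoker and non-drinker", "smoker")
        d2 = _decide(lex, "She is a non-smoker and non-drinker", "drinker")
        for d in (d1, d2):
            assert d.polarity is Polarity.NEGATIVE and d.rule_fired is Rule.SEMANTIC_WORD

    def test_minus_sign_negates(self, lex):
        d = _decide(lex, "-tob", "tob")
        assert d.polarity is Polarity.NEGATIVE and d.rule_fired is Rule.SIGN

    def test_plus_sign_forces_positive(self, lex):
        d = _decide(lex, "no +etho", "etho")
        assert d.polarity is Polarity.POSITIVE and d.rule_fired is Rule.SIGN

    def test_ex_hyphen_is_not_a_sign(self, lex):
        d = _decide(lex, "ex-smoker", "smoker")
        assert d.rule_fired is not Rule.SIGN
        assert d.polarity is Polarity.POSITIVE  # past semantics handled in stage 3

    def test_header_none(self, lex):
        d = _decide(lex, "Alcohol: None", "alcohol")
        assert d.polarity is Polarity.NEGATIVE and d.rule_fired is Rule.HEADER_NONE

    def test_header_requires_negated_body(self, lex):
        d = _decide(lex, "Alcohol: drinks wine daily", "alcohol")
        assert d.polarity is Polarity.POSITIVE

    def test_nor_expansion_reaches_first_keyword(self, lex):
        d_alcohol = _decide(lex, "She does not consume alcohol, nor does she smoke", "alcohol")
        d_smoke = _decide(lex, "She does not consume alcohol, nor does she smoke", "smoke")
        assert d_alcohol.polarity is Polarity.NEGATIVE
        assert d_alcohol.rule_fired is Rule.NEGEX_WINDOW
        assert d_smoke.polarity is Polarity.NEGATIVE
        assert d_smoke.rule_fired is Rule.NOR_EXPANSION

    def test_social_override_rescues_adjacent_keyword_only(self, lex):
        d_smoke = _decide(lex, "denies smoke, alcohol socially", "smoke")
        d_alcohol = _decide(lex, "denies smoke, alcohol socially", "alcohol")
        assert d_smoke.polarity is Polarity.NEGATIVE
        assert d_alcohol.polarity is Polarity.POSITIVE
        assert d_alcohol.rule_fired is Rule.OVERRIDE_SOCIAL

    def test_temporal_override_carries_past_hint(self, lex):
        d = _decide(lex, "he has not drunk alcohol since 1984", "alcohol")
        assert d.polarity is Polarity.POSITIVE
        assert d.rule_fired is Rule.OVERRIDE_TEMPORAL
        assert d.past_hint

    def test_default_positive(self, lex):
        d = _decide(lex, "He smokes", "smokes")
        assert d.polarity is Polarity.POSITIVE and d.rule_fired is Rule.DEFAULT_POSITIVE

    def test_active_denies_does_not_negate_backwards(self, lex):
        d = _decide(lex, "he is a former smoker, he denies any use of tobacco", "smoker")
        assert d.polarity is Polarity.POSITIVE


class TestDocumentedFailures:
    def test_right_window_overreach(self, classify):
        """"Smoking, no alcohol": "no" falls in smoking's right window too."""
        got = classify("Smoking, no alcohol.")
        assert got["smoking"] == "NONE" and got["alcohol"] == "NONE"

    def test_far_trigger_missed(self, classify):
        """"drugs" sits beyond the two-word right window of "denied"."""
        got = classify("Abuse of drugs or alcohol were denied.")
        assert got["alcohol"] == "NONE"
        assert got["drugs"] == "CURRENT"

    def test_misspelled_keyword_not_recognised(self, classify):
        assert classify("History of barbituate abuse.")["drugs"] == "UNKNOWN"


class TestScopes:
    @pytest.mark.parametrize("gap", range(1, 13))
    def test_left_scope_boundary(self, lex, gap):
        """A pre-trigger fires iff the keyword is within 9 words after it."""
        fillers = " ".join(["pad"] * (gap - 1))
        text = ("denies " + (fillers + " " if fillers else "") + "tobacco").strip()
        d = _decide(lex, text, "tobacco")
        expected = Polarity.NEGATIVE if gap <= 9 else Polarity.POSITIVE
        assert d.polarity is expected

    @pytest.mark.parametrize("gap", range(1, 5))
    def test_right_scope_boundary(self, lex, gap):
        """A post-trigger fires iff it is within 2 words after the keyword."""
        fillers = " ".join(["pad"] * (gap - 1))
        text = ("tobacco " + (fillers + " " if fillers else "") + "denied").strip()
        d = _decide(lex, text, "tobacco")
        expected = Polarity.NEGATIVE if gap <= 2 else Polarity.POSITIVE
        assert d.polarity is expected

    @pytest.mark.parametrize("left,right", [(0, 0), (3, 1), (12, 4)])
    def test_custom_scopes_respected(self, lex, left, right):
        cfg = NegationConfig(max_left_scope=left, max_right_scope=right)
        for gap in range(1, 14):
            fillers = " ".join(["pad"] * (gap - 1))
            text = ("denies " + (fillers + " " if fillers else "") + "tobacco").strip()
            d = _decide(lex, text, "tobacco", cfg)
            assert (d.polarity is Polarity.NEGATIVE) == (gap <= left)

    def test_scope_zero_disables_negation(self, classify):
        cfg = NegationConfig(max_left_scope=0, max_right_scope=0)
        assert classify("denies tobacco.", cfg=cfg)["smoking"] == "CURRENT"


class TestAggregation:
    def _dec(self, polarity):
        return PolarityDecision(mention=None, polarity=polarity, rule_fired=Rule.DEFAULT_POSITIVE)

    def test_or_any_positive_wins(self):
        decisions = [self._dec(Polarity.NEGATIVE), self._dec(Polarity.POSITIVE)]
        assert aggregate_polarity(decisions) is Polarity.POSITIVE

    def test_all_negative_is_negative(self):
        decisions = [self._dec(Polarity.NEGATIVE)] * 3
        assert aggregate_polarity(decisions) is Polarity.NEGATIVE

    def test_empty_decisions_rejected(self):
        with pytest.raises(ValueError):
            aggregate_polarity([])

    def test_or_monotonic_over_all_pairs(self):
        for a in Polarity:
            for b in Polarity:
                agg = aggregate_polarity([self._dec(a), self._dec(b)])
                expected = (
                    Polarity.POSITIVE
                    if Polarity.POSITIVE in (a, b)
                    else Polarity.NEGATIVE
                )
                assert agg is expected

    def test_conflicting_keywords_resolve_positive(self, classify):
        got = classify("he is a former smoker, he denies any use of tobacco.")
        assert got["smoking"] == "PAST"


class TestBaselineContrast:
    """With the seven extensions disabled, the rule examples come out wrong."""

    @pytest.mark.parametrize(
        "text,substance,extended,plain",
        [
            ("She is a non-smoker and non-drinker.", "smoking", "NONE", "CURRENT"),
            ("She is a non-smoker and non-drinker.", "alcohol", "NONE", "CURRENT"),
            ("-tob.", "smoking", "NONE", "CURRENT"),
            ("She does not consume alcohol, nor does she smoke.", "smoking", "NONE", "CURRENT"),
            ("Alcohol: None.", "alcohol", "NONE", "CURRENT"),
            ("denies smoke, alcohol socially.", "alcohol", "CURRENT", "NONE"),
            ("he has not drunk alcohol since 1984.", "alcohol", "PAST", "NONE"),
            ("he is a former smoker, he denies any use of tobacco.", "smoking", "PAST", "NONE"),
        ],
    )
    def test_extension_is_the_active_ingredient(self, classify, text, substance, extended, plain):
        assert classify(text)[substance] == extended
        baseline = classify(text, cfg=NegationConfig(extensions=False))
        assert baseline[substance] == plain

    def test_exactly_one_rule_recorded(self, lex):
        for text, kw in [
            ("denies tobacco", "tobacco"),
            ("-tob", "tob"),
            ("nonsmoker", "smoker"),
            ("smokes", "smokes"),
        ]:
            d = _decide(lex, text, kw)
            assert isinstance(d.rule_fired, Rule)
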