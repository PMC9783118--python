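"""Stage 4: amount scans, type lexicon, frequency patterns, quit-time/period."""

import pytest

from substex.model import Record, SourceScan, Status, Substance
from substex.pipeline import run_record

S, A, D = Substance.SMOKING, Substance.ALCOHOL, Substance.DRUG


class TestAmountScans:
    @pytest.mark.parametrize(
        "text,span",
        [
            ("smokes 1 to 2 packs.", "1 to 2 packs"),
            ("drinks 3–4 drinks.", "3–4 drinks"),
            ("drinks 1-2 beers.", "1-2 beers"),
            ("Smoked 100 pk.", "100 pk"),
            ("smoked 2 and 1/2 to 3 packs.", "2 and 1/2 to 3 packs"),
            ("smokes 2 ppd.", "2 ppd"),
        ],
    )
    def test_numeric_regex_scan(self, attributes_of, text, span):
        assert any(k == "AMOUNT" and t == span for _, k, t in attributes_of(text))

    @pytest.mark.parametrize(
        "text,span",
        [
            ("smokes five packs.", "five packs"),
            ("drinks two to three beers.", "two to three beers"),
            ("drinks up to one pint.", "up to one pint"),
            ("drinks two gallons of gin.", "two gallons"),
        ],
    )
    def test_spelled_syntactic_scan(self, attributes_of, text, span):
        assert any(k == "AMOUNT" and t == span for _, k, t in attributes_of(text))

    @pytest.mark.parametrize("text,span", [("heavy tob use.", "heavy")])
    def test_lexical_scan(self, attributes_of, text, span):
        assert ("smoking", "AMOUNT", span) in attributes_of(text)

    def test_scan_precedence_numeric_beats_lexical(self, lex):
        result = run_record(Record("t", "heavy smoker, 2 packs."), lex)
        amounts = [a for a in result.results[S].attributes if a.kind.value == "AMOUNT"]
        assert [a.text for a in amounts] == ["2 packs"]
        assert amounts[0].source_scan is SourceScan.REGEX


class TestTypes:
    @pytest.mark.parametrize(
        "text,substance,types",
        [
            ("pipe and cigar smoker.", "smoking", {"pipe", "cigar"}),
            ("drinks gin and vodka.", "alcohol", {"gin", "vodka"}),
            ("uses marijuana.", "drugs", {"marijuana"}),
            ("drinks glasses of scotch.", "alcohol", {"scotch"}),
        ],
    )
    def test_type_sub_lexicon(self, attributes_of, text, substance, types):
        got = {t for sub, k, t in attributes_of(text) if sub == substance and k == "TYPE"}
        assert got == types


class TestFrequency:
    @pytest.mark.parametrize(
        "text,span",
        [
            ("smokes 2 ppd per day.", "per day"),
            ("drinks one to two times a month.", "one to two times a month"),
            ("smokes 2 packs/years.", "/years"),
            ("drinks 1-2 beers every week.", "every week"),
        ],
    )
    def test_pattern_pass(self, attributes_of, text, span):
        assert any(k == "FREQUENCY" and t == span for _, k, t in attributes_of(text))

    @pytest.mark.parametrize(
        "text,span",
        [
            ("drinks alcohol occasionally.", "occasionally"),
            ("drinks wine nightly.", "nightly"),
            ("smokes occ.", "occ"),
        ],
    )
    def test_lexical_fallback(self, attributes_of, text, span):
        assert any(k == "FREQUENCY" and t == span for _, k, t in attributes_of(text))

    def test_connector_alone_needs_amount_or_times(self, attributes_of):
        # "a day" without a preceding amount value must not become a frequency
        got = attributes_of("smokes more than once a day sometimes.")
        assert not any(k == "FREQUENCY" for _, k, t in got)


class TestQuitAndPeriod:
    @pytest.mark.parametrize(
        "text,kind,span",
        [
            ("He stopped smoking in 1994.", "QUIT_TIME", "1994"),
            ("quit alcohol 25 years ago.", "QUIT_TIME", "25 years ago"),
            ("last drink 3/2/05.", "QUIT_TIME", "3/2/05"),
            ("tobacco, none since 1967.", "QUIT_TIME", "1967"),
            ("last use of heroin seven years ago.", "QUIT_TIME", "seven years ago"),
            ("smoked ×35 years.", "PERIOD", "×35 years"),
            ("smoked × 20 yrs.", "PERIOD", "× 20 yrs"),
            ("smoked for 30 years.", "PERIOD", "for 30 years"),
            ("drank for 8 to 9 years.", "PERIOD", "for 8 to 9 years"),
            ("smoked tobacco times 33 years.", "PERIOD", "times 33 years"),
            ("used cocaine for three years.", "PERIOD", "for three years"),
        ],
    )
    def test_patterns(self, attributes_of, text, kind, span):
        assert any(k == kind and t == span for _, k, t in attributes_of(text))

    def test_period_connector_blocks_quit_claim(self, attributes_of):
        got = attributes_of("stopped smoking for 30 years.")
        kinds = {(k, t) for _, k, t in got}
        assert ("PERIOD", "for 30 years") in kinds
        assert not any(k == "QUIT_TIME" for k, _ in kinds)


class TestAssignment:
    def test_quit_time_goes_to_adjacent_substance(self, lex):
        text = "smokes 1 ppd, drinks socially; quit tobacco 5 years ago."
        result = run_record(Record("t", text), lex)
        quit_subs = [
            sub.json_key
            for sub in (S, A, D)
            for a in result.results[sub].attributes
            if a.kind.value == "QUIT_TIME"
        ]
        assert quit_subs == ["smoking"]

    def test_nearest_prior_tie_break(self, lex):
        text = "cocaine and alcohol abuse for three years."
        result = run_record(Record("t", text), lex)
        periods = [
            (sub.json_key, a.text)
            for sub in (S, A, D)
            for a in result.results[sub].attributes
            if a.kind.value == "PERIOD"
        ]
        assert periods == [("alcohol", "for three years")]

    def test_single_substance_takes_all_spans(self, lex):
        text = "He smokes 1 to 2 packs per day."
        result = run_record(Record("t", text), lex)
        assert {a.kind.value for a in result.results[S].attributes} == {
            "AMOUNT",
            "FREQUENCY",
        }

    def test_orphan_quit_sentence_inherits_substance(self, lex):
        text = "He smokes cigarettes. Quit 10 years ago."
        result = run_record(Record("t", text), lex)
        kinds = {(a.kind.value, a.text) for a in result.results[S].attributes}
        assert ("QUIT_TIME", "10 years ago") in kinds


class TestInvariants:
    @pytest.mark.parametrize(
        "text",
        [
            "He smokes 1 to 2 packs per day.",
            "quit alcohol 25 years ago.",
            "smoked ×35 years and drank for 8 to 9 years.",
            "drinks two gallons of gin and vodka one to two times a month.",
        ],
    )
    def test_span_offsets_slice_cleanly(self, lex, text):
        result = run_record(Record("t", text), lex)
        for sub in (S, A, D):
            for a in result.results[sub].attributes:
                assert text[a.char_start:a.char_end] == a.text

    def test_no_attributes_for_unknown_or_none(self, lex):
        for text in ["Denies tobacco use entirely.", "No alcohol or drugs."]:
            result = run_record(Record("t", text), lex)
            for sub in (S, A, D):
                if result.results[sub].status in (Status.UNKNOWN, Status.NONE):
                    assert result.results[sub].attributes == []

    def test_drug_frequency_machinery_does_not_crash(self, lex):
        result = run_record(Record("t", "uses cocaine daily."), lex)
        assert result.results[D].status is Status.CURRENT
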