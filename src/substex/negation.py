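"""Stage 2: extended NegEx polarity assignment for substance mentions.

The base algorithm is window NegEx: a negation trigger within a bounded
word distance of the keyword (9 words before, 2 after, by default) marks it
negated, with conjunctions ("nor", "but") terminating a trigger's forward
scope. Seven extensions are layered on top: semantic negation words
(non-smoker), polarity signs (-tob / +etho), header negation
("Alcohol: None"), the nor-expansion, social and temporal negation
overrides, and OR aggregation (any positive mention makes the sentence and
document positive). A temporal override ("not ... since 1984") both cancels
the negation and marks the mention as past evidence for Stage 3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .lexicons import LexiconSet
from .model import Mention, Section, Sentence
from .relevance import match_term_spans
from .preprocess import word_positions

#: conjunctions that terminate a negation trigger's scope
SCOPE_TERMINATORS = frozenset({"nor", "but"})

HEADER_NEGATION_WORDS = frozenset({"none", "no", "denies", "denied", "never"})


class Rule(enum.Enum):
    NEGEX_WINDOW = "NEGEX_WINDOW"
    SEMANTIC_WORD = "SEMANTIC_WORD"
    SIGN = "SIGN"
    NOR_EXPANSION = "NOR_EXPANSION"
    HEADER_NONE = "HEADER_NONE"
    OVERRIDE_SOCIAL = "OVERRIDE_SOCIAL"
    OVERRIDE_TEMPORAL = "OVERRIDE_TEMPORAL"
    DEFAULT_POSITIVE = "DEFAULT_POSITIVE"


class Polarity(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass
class NegationConfig:
    max_left_scope: int = 9
    max_right_scope: int = 2
    extensions: bool = True  # False = plain window NegEx (baseline behaviour)

    def __post_init__(self) -> None:
        if self.max_left_scope < 0 or self.max_right_scope < 0:
            raise ValueError("negation scopes must be non-negative")


@dataclass
class PolarityDecision:
    mention: Mention
    polarity: Polarity
    rule_fired: Rule
    past_hint: bool = False  # temporal override implies prior (past) use


def _terminator_between(sentence: Sentence, lo: int, hi: int) -> bool:
    return any(
        t.norm in SCOPE_TERMINATORS for t in sentence.tokens[lo + 1:hi] if t.is_word
    )


def polarity_of_mention(
    mention: Mention,
    sentence: Sentence,
    sections: list[Section],
    lex: LexiconSet,
    cfg: NegationConfig,
    sentence_mentions: Optional[list[Mention]] = None,
) -> PolarityDecision:
    """Assign polarity to one active mention; exactly one rule is recorded."""
    toks = sentence.tokens
    kw_start, kw_end = mention.token_span
    first_tok = toks[kw_start]
    wpos = word_positions(sentence)
    active = [m for m in (sentence_mentions or []) if m.active and m is not mention]

    if cfg.extensions:
        # rule 1: the keyword itself is a semantic negation ("non-drinker")
        if first_tok.norm in lex.semantic_negation_words:
            return PolarityDecision(mention, Polarity.NEGATIVE, Rule.SEMANTIC_WORD)
        # rule 2: attached polarity sign (-tob, +etho); hyphen compounds are not signs
        if first_tok.text.startswith("-") and len(first_tok.text) > 1:
            return PolarityDecision(mention, Polarity.NEGATIVE, Rule.SIGN)
        if first_tok.text.startswith("+") and len(first_tok.text) > 1:
            return PolarityDecision(mention, Polarity.POSITIVE, Rule.SIGN)
        # rule 3 (header): keyword inside a section header whose body starts negated
        header_dec = _header_negation(mention, sentence, sections)
        if header_dec is not None:
            return PolarityDecision(mention, Polarity.NEGATIVE, Rule.HEADER_NONE)

    # window NegEx: a pre-trigger within the left scope or a post-trigger
    # within the right scope, not across a scope terminator
    candidate: Optional[Rule] = None
    trigger_span: Optional[tuple[int, int]] = None
    for words, t_start, t_end in match_term_spans(sentence, lex.negation_triggers):
        if t_end <= kw_start:
            d = wpos[kw_start] - wpos[toks[t_end - 1].index]
            if 1 <= d <= cfg.max_left_scope and not _terminator_between(
                sentence, t_end - 1, kw_start
            ):
                candidate, trigger_span = Rule.NEGEX_WINDOW, (t_start, t_end)
                break
    if candidate is None:
        for words, t_start, t_end in match_term_spans(sentence, lex.negation_post_triggers):
            if t_start >= kw_end:
                d = wpos[t_start] - wpos[toks[kw_end - 1].index]
                if 1 <= d <= cfg.max_right_scope and not _terminator_between(
                    sentence, kw_end - 1, t_start
                ):
                    candidate, trigger_span = Rule.NEGEX_WINDOW, (t_start, t_end)
                    break

    # rule 4 (nor expansion): "nor" negates the first keyword appearing after it
    if candidate is None and cfg.extensions:
        for t in toks[:kw_start]:
            if t.norm == "nor":
                first_after = min(
                    (m.token_span[0] for m in active if m.token_span[0] > t.index),
                    default=kw_start,
                )
                if kw_start <= first_after:
                    candidate, trigger_span = Rule.NOR_EXPANSION, (t.index, t.index + 1)
                break

    if candidate is not None:
        if cfg.extensions:
            override = _override(mention, sentence, trigger_span, active, lex, cfg)
            if override is Rule.OVERRIDE_SOCIAL:
                return PolarityDecision(mention, Polarity.POSITIVE, override)
            if override is Rule.OVERRIDE_TEMPORAL:
                return PolarityDecision(mention, Polarity.POSITIVE, override, past_hint=True)
        return PolarityDecision(mention, Polarity.NEGATIVE, candidate)

    return PolarityDecision(mention, Polarity.POSITIVE, Rule.DEFAULT_POSITIVE)


def _header_negation(
    mention: Mention, sentence: Sentence, sections: list[Section]
) -> Optional[Section]:
    for sec in sections:
        if sec.header_char_start <= mention.char_start and mention.char_end <= sec.header_char_end:
            body_words = [
                t for t in sentence.tokens if t.is_word and t.char_start >= sec.header_char_end
            ]
            if body_words and body_words[0].norm in HEADER_NEGATION_WORDS:
                return sec
    return None


def _closest_preceding_is_me(
    mention: Mention, others: list[Mention], term_index: int
) -> bool:
    """True iff *mention* is the nearest substance keyword before token *term_index*."""
    if mention.token_span[1] > term_index:
        return False
    return not any(
        mention.token_span[1] <= m.token_span[1] <= term_index for m in others
    )


def _override(
    mention: Mention,
    sentence: Sentence,
    trigger_span: Optional[tuple[int, int]],
    others: list[Mention],
    lex: LexiconSet,
    cfg: NegationConfig,
) -> Optional[Rule]:
    toks = sentence.tokens
    wpos = word_positions(sentence)
    kw_start, kw_end = mention.token_span
    # social override: term right after THIS keyword (it must be the closest
    # preceding keyword, so "denies smoke, alcohol socially" rescues alcohol only)
    for t in toks:
        if (
            t.is_word
            and t.norm in lex.overrides_social
            and t.index >= kw_end
            and wpos[t.index] - wpos[toks[kw_end - 1].index] <= max(cfg.max_right_scope, 1)
            and _closest_preceding_is_me(mention, others, t.index)
        ):
            return Rule.OVERRIDE_SOCIAL
    # temporal override: term between the trigger and the keyword, or shortly
    # after the keyword (with no other keyword in between)
    trig_end = trigger_span[1] - 1 if trigger_span else None
    for t in toks:
        if not t.is_word or t.norm not in lex.overrides_temporal:
            continue
        between = (
            trig_end is not None
            and toks[trig_end].index < t.index < kw_start
        )
        after = (
            t.index >= kw_end
            and wpos[t.index] - wpos[toks[kw_end - 1].index] <= cfg.max_left_scope
            and _closest_preceding_is_me(mention, others, t.index)
        )
        if between or after:
            return Rule.OVERRIDE_TEMPORAL
    return None


def aggregate_polarity(decisions: list[PolarityDecision], extended: bool = True) -> Polarity:
    """Combine per-mention polarities for one substance at one level.

    Extended mode applies the OR rule: positive wherever any positive mention
    exists. Baseline (plain NegEx) mode is negative-dominant, matching the
    behaviour the extension was introduced to correct.
    """
    if not decisions:
        raise ValueError("aggregate_polarity requires at least one decision")
    if extended:
        return (
            Polarity.POSITIVE
            if any(d.polarity is Polarity.POSITIVE for d in decisions)
            else Polarity.NEGATIVE
        )
    return (
        Polarity.NEGATIVE
        if any(d.polarity is Polarity.NEGATIVE for d in decisions)
        else Polarity.POSITIVE
    )
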