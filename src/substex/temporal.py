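"""Stage 3: classify positive mentions as PAST or CURRENT.

Positive mentions default to CURRENT unless clear past evidence links to
them: a past term fired under its scope rule (same chunk, one word after,
two words either side, all words before, or one-after-else-all-before), an
"ex-" prefixed keyword, or a temporal negation override carried over from
Stage 2. Treatment terms ("nicotine patch", "smoking cessation") and
intent phrases ("to quit", "to stop") mark the sentence as current and
override past evidence within that sentence. When several substances share
a sentence, a past term attaches to the closest mention (ties break toward
the mention before the term). The document status per substance is CURRENT
if any of its mentions is CURRENT, else PAST.
"""

from __future__ import annotations

from .lexicons import LexiconSet, PastScope, PastTermRule
from .model import Chunk, Mention, Sentence, Status, Substance
from .negation import PolarityDecision, Polarity
from .preprocess import chunk_of, word_positions
from .relevance import QuitLink, match_term_spans


def _scope_satisfied(
    rule: PastTermRule,
    term_span: tuple[int, int],
    mention: Mention,
    sentence: Sentence,
    chunks: list[Chunk],
) -> bool:
    t_start, t_end = term_span
    k_start, k_end = mention.token_span
    toks = sentence.tokens
    wpos = word_positions(sentence)

    def one_after() -> bool:
        # keyword is the next word token after the term
        after = [t for t in toks[t_end:] if t.is_word]
        return bool(after) and after[0].index == k_start

    if rule.scope is PastScope.SAME_CHUNK:
        kc = chunk_of(chunks, k_start)
        return all(
            chunk_of(chunks, i) is kc for i in range(t_start, t_end) if toks[i].is_word
        )
    if rule.scope is PastScope.ONE_AFTER:
        return one_after()
    if rule.scope is PastScope.TWO_BEFORE_TWO_AFTER:
        if k_end <= t_start:
            d = wpos[toks[t_start].index] - wpos[toks[k_end - 1].index]
        elif t_end <= k_start:
            d = wpos[toks[k_start].index] - wpos[toks[t_end - 1].index]
        else:
            d = 0
        return d <= 2
    if rule.scope is PastScope.ALL_BEFORE:
        return k_end <= t_start
    if rule.scope is PastScope.ONE_AFTER_ELSE_ALL_BEFORE:
        return one_after() or k_end <= t_start
    raise AssertionError(rule.scope)


def past_evidence(
    mention: Mention,
    sentence: Sentence,
    chunks: list[Chunk],
    rules: tuple[PastTermRule, ...],
) -> bool:
    """True iff some past term links to the mention under its scope rule."""
    if mention.is_ex_prefixed:
        return True
    rule_by_term = {r.term: r for r in rules}
    for words, t_start, t_end in match_term_spans(sentence, set(rule_by_term)):
        rule = rule_by_term[" ".join(words)]
        if _scope_satisfied(rule, (t_start, t_end), mention, sentence, chunks):
            return True
    return False


def current_indicator(sentence: Sentence, substance: Substance, lex: LexiconSet) -> bool:
    """True iff a current-use indicator for the substance occurs in the sentence."""
    for words, _, _ in match_term_spans(sentence, set(lex.current_indicator_terms)):
        target = lex.current_indicator_terms[" ".join(words)]
        if target == "ANY" or target == substance.json_key:
            return True
    return False


def assign_past_to_closest(
    sentence: Sentence,
    term_span: tuple[int, int],
    candidates: list[Mention],
) -> Mention:
    """Pick the mention a past term attaches to: minimal word distance,
    ties broken toward the mention before the term."""
    wpos = word_positions(sentence)
    toks = sentence.tokens
    t_lo = wpos[toks[term_span[0]].index]
    t_hi = wpos[toks[term_span[1] - 1].index]

    def key(m: Mention):
        k_lo = wpos[toks[m.token_span[0]].index]
        k_hi = wpos[toks[m.token_span[1] - 1].index]
        if k_hi < t_lo:
            dist, before = t_lo - k_hi, 0
        elif k_lo > t_hi:
            dist, before = k_lo - t_hi, 1
        else:
            dist, before = 0, 0
        return (dist, before)

    return min(candidates, key=key)


def mention_past_links(
    sentence: Sentence,
    chunks: list[Chunk],
    positive_mentions: list[Mention],
    rules: tuple[PastTermRule, ...],
) -> set[int]:
    """Token-start indices of mentions that receive past evidence in a sentence."""
    linked: set[int] = set()
    for m in positive_mentions:
        if m.is_ex_prefixed:
            linked.add(m.token_span[0])
    rule_by_term = {r.term: r for r in rules}
    for words, t_start, t_end in match_term_spans(sentence, set(rule_by_term)):
        rule = rule_by_term[" ".join(words)]
        candidates = [
            m
            for m in positive_mentions
            if _scope_satisfied(rule, (t_start, t_end), m, sentence, chunks)
        ]
        if not candidates:
            continue
        if len({m.substance for m in candidates}) > 1:
            winner = assign_past_to_closest(sentence, (t_start, t_end), candidates)
            linked.add(winner.token_span[0])
        else:
            linked.update(m.token_span[0] for m in candidates)
    return linked


def temporal_status(
    sentences: list[Sentence],
    chunks_by_sentence: dict[int, list[Chunk]],
    positive_decisions: list[PolarityDecision],
    quit_links: list[QuitLink],
    lex: LexiconSet,
) -> tuple[dict[Substance, Status], dict[tuple[int, int], Status]]:
    """Per-substance document temporal status plus per-mention statuses.

    Returns (document status map over substances with positive mentions,
    per-mention status keyed by (sentence_index, token_start)).
    """
    by_sentence: dict[int, list[PolarityDecision]] = {}
    for d in positive_decisions:
        assert d.polarity is Polarity.POSITIVE
        by_sentence.setdefault(d.mention.sentence_index, []).append(d)

    sent_by_idx = {s.index: s for s in sentences}
    mention_status: dict[tuple[int, int], Status] = {}
    for s_idx, decisions in by_sentence.items():
        sent = sent_by_idx[s_idx]
        chunks = chunks_by_sentence[s_idx]
        mentions = [d.mention for d in decisions]
        linked = mention_past_links(sent, chunks, mentions, lex.past_term_rules)
        for d in decisions:
            m = d.mention
            has_past = d.past_hint or m.token_span[0] in linked
            if has_past and not current_indicator(sent, m.substance, lex):
                mention_status[(s_idx, m.token_span[0])] = Status.PAST
            else:
                mention_status[(s_idx, m.token_span[0])] = Status.CURRENT

    # an orphan "quit" sentence contributes past evidence to the substances
    # of the sentence it was linked to
    quit_past: dict[Substance, bool] = {}
    for link in quit_links:
        sent = sent_by_idx[link.quit_sentence]
        for sub in link.substances:
            if not current_indicator(sent, sub, lex):
                quit_past[sub] = True

    doc_status: dict[Substance, Status] = {}
    for d in positive_decisions:
        sub = d.mention.substance
        key = (d.mention.sentence_index, d.mention.token_span[0])
        st = mention_status[key]
        if (
            st is Status.CURRENT
            and quit_past.get(sub)
            and not current_indicator(sent_by_idx[d.mention.sentence_index], sub, lex)
        ):
            st = Status.PAST
            mention_status[key] = st
        prev = doc_status.get(sub)
        if prev is None:
            doc_status[sub] = st
        elif st is Status.CURRENT or prev is Status.CURRENT:
            doc_status[sub] = Status.CURRENT
    return doc_status, mention_status
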