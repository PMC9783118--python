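"""Stage 1: find substance-keyword mentions and gate records as Known/Unknown.

Every token-sequence match of a substance keyword becomes a Mention; four
suppression passes then run in a fixed order (MISLEADING, SECTION,
NON_ALCOHOLIC, PPD_UNQUALIFIED). A record with no active mention of any
substance is Unknown for all three classes and is discarded before the
later stages.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicons import LexiconSet
from .model import Chunk, Mention, Sentence, Substance, SuppressionReason
from .preprocess import chunk_of, shallow_chunk


def _norm_forms(token_text: str) -> list[tuple[str, str]]:
    """Normalized lookup forms of a token, tagged with the prefix stripped.

    Lower-cases, strips an attached polarity sign, and offers the stem of
    "ex-"/"non-" prefixed compounds ("ex-smoker" -> "smoker") so prefixed
    keywords still anchor a mention. The tag is "" (no prefix), "ex" or "non".
    """
    t = token_text.lower()
    if t and t[0] in "+-":
        t = t[1:]
    forms = [(t, "")]
    if t.startswith("ex-") and len(t) > 3:
        forms.append((t[3:], "ex"))
    if t.startswith("non-") and len(t) > 4:
        forms.append((t[4:], "non"))
    elif t.startswith("non") and len(t) > 6:
        forms.append((t[3:], "non"))
    return forms


def _term_index(terms: set[str] | frozenset[str]) -> dict[str, list[tuple[str, ...]]]:
    index: dict[str, list[tuple[str, ...]]] = {}
    for term in terms:
        words = tuple(term.split())
        index.setdefault(words[0], []).append(words)
    for v in index.values():
        v.sort(key=len, reverse=True)  # longest match first
    return index


def match_term_spans(
    sentence: Sentence, terms: set[str] | frozenset[str]
) -> list[tuple[tuple[str, ...], int, int]]:
    """Greedy longest token-sequence matches of *terms* in one sentence.

    Returns (term words, token_start, token_end) triples; multi-word terms
    must appear as consecutive tokens.
    """
    index = _term_index(terms)
    toks = sentence.tokens
    matches = []
    p = 0
    while p < len(toks):
        forms = {f for f, _ in _norm_forms(toks[p].text)}
        hit = None
        for first, candidates in index.items():
            if first not in forms:
                continue
            for words in candidates:
                if p + len(words) > len(toks):
                    continue
                ok = all(
                    words[k] in {f for f, _ in _norm_forms(toks[p + k].text)}
                    for k in range(len(words))
                )
                if ok and (hit is None or len(words) > len(hit)):
                    hit = words
        if hit is not None:
            matches.append((hit, p, p + len(hit)))
            p += len(hit)
        else:
            p += 1
    return matches


DRINK_FORMS = frozenset({"drink", "drinks", "drinking", "drank"})


def find_mentions(
    sentences: list[Sentence],
    lex: LexiconSet,
    record_text: str,
    chunks_by_sentence: dict[int, list[Chunk]] | None = None,
) -> list[Mention]:
    """Locate keyword mentions and apply the four suppression passes in order."""
    substance_of: dict[str, Substance] = {}
    for sub in Substance:
        for kw in lex.keywords_for(sub):
            substance_of.setdefault(kw, sub)

    mentions: list[Mention] = []
    for sent in sentences:
        chunks = (
            chunks_by_sentence[sent.index]
            if chunks_by_sentence is not None
            else shallow_chunk(sent)
        )
        misleading = match_term_spans(sent, lex.misleading_concepts)
        for words, t_start, t_end in match_term_spans(sent, lex.all_keywords):
            term = " ".join(words)
            sub = substance_of[term]
            first_tok = sent.tokens[t_start]
            ex_prefixed = any(
                tag == "ex" and form == words[0] for form, tag in _norm_forms(first_tok.text)
            )
            m = Mention(
                substance=sub,
                keyword=term,
                sentence_index=sent.index,
                token_span=(t_start, t_end),
                char_start=first_tok.char_start,
                char_end=sent.tokens[t_end - 1].char_end,
                is_ex_prefixed=ex_prefixed,
            )
            reason = _suppression_reason(m, sent, chunks, misleading, lex)
            if reason is not SuppressionReason.NONE:
                m.suppressed = True
                m.suppression_reason = reason
            mentions.append(m)
    return mentions


def _suppression_reason(
    m: Mention,
    sent: Sentence,
    chunks: list[Chunk],
    misleading: list[tuple[tuple[str, ...], int, int]],
    lex: LexiconSet,
) -> SuppressionReason:
    # (a) inside a misleading-concept phrase
    for _, ms, me in misleading:
        if ms <= m.token_span[0] and m.token_span[1] <= me:
            return SuppressionReason.MISLEADING
    # (b) alcohol/drug mention in a restricted section
    if sent.section in lex.restricted_sections.get(m.substance, frozenset()):
        return SuppressionReason.SECTION
    # (c) "drink" deactivated by an adjacent non-alcoholic drink
    if m.substance is Substance.ALCOHOL and m.keyword in DRINK_FORMS:
        my_chunk = chunk_of(chunks, m.token_span[0])
        my_pos = chunks.index(my_chunk)
        nearby = chunks[max(0, my_pos - 1):my_pos + 2]
        for c in nearby:
            for k in range(c.token_span[0], c.token_span[1]):
                if sent.tokens[k].norm in lex.non_alcoholic_drinks:
                    return SuppressionReason.NON_ALCOHOLIC
    # (d) "ppd" counts as smoking only when preceded by a number
    if m.keyword == "ppd":
        prev_words = [t for t in sent.tokens[:m.token_span[0]] if t.is_word]
        if not prev_words or prev_words[-1].pos_tag != "CD":
            return SuppressionReason.PPD_UNQUALIFIED
    return SuppressionReason.NONE


@dataclass
class QuitLink:
    """A sentence containing "quit" but no mention, linked to an earlier one."""

    quit_sentence: int
    linked_sentence: int
    substances: tuple[Substance, ...]


def attach_orphan_quit(sentences: list[Sentence], mentions: list[Mention]) -> list[QuitLink]:
    """Link keyword-less "quit" sentences to the nearest preceding mention."""
    active_by_sentence: dict[int, list[Mention]] = {}
    for m in mentions:
        if m.active:
            active_by_sentence.setdefault(m.sentence_index, []).append(m)

    links = []
    for sent in sentences:
        has_quit = any(t.norm == "quit" for t in sent.tokens)
        if not has_quit or sent.index in active_by_sentence:
            continue
        for prev in range(sent.index - 1, -1, -1):
            if prev in active_by_sentence:
                subs = tuple(dict.fromkeys(m.substance for m in active_by_sentence[prev]))
                links.append(QuitLink(sent.index, prev, subs))
                break
    return links


def classify_known(mentions: list[Mention]) -> dict[Substance, bool]:
    """A substance is Known iff at least one active mention of it exists."""
    known = {sub: False for sub in Substance}
    for m in mentions:
        if m.active:
            known[m.substance] = True
    return known
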