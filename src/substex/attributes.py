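"""Stage 4: extract amount, type, frequency, quit-time and period spans.

Amounts run through three scans with strict precedence: numeric regex
patterns ("1 to 2 packs", "3–4 drinks"), then syntactic patterns over
spelled-out cardinals ("two to three beers", "up to one pint"), then
lexical descriptors ("heavy", "minimal"). Frequencies follow the
``(amount | times) (per|a|/|every|-) (day|week|month|year)`` pattern with a
lexical fallback ("occ", "nightly"). Quit-times anchor on a quit verb
(quit/stop/discontinued/until/since/last <use>) followed closely by a
cardinal, or on a bare "<CD> years ago"; periods anchor on
for/times/×/x followed by a cardinal and a period word. All spans carry
absolute character offsets into the raw record text.
"""

from __future__ import annotations

import re

from .lexicons import LexiconSet
from .model import (
    AttributeKind,
    AttributeSpan,
    Chunk,
    Mention,
    Sentence,
    SourceScan,
    Substance,
)
from .preprocess import SPELLED_NUMBERS, chunk_of, word_positions
from .relevance import match_term_spans

_NUM = r"\d+(?:\.\d+)?(?:/\d+)?"
_AMT_NUM = rf"{_NUM}(?:\s+and\s+{_NUM})?(?:\s*(?:-|–|to)\s*{_NUM})?"
_SP = "|".join(sorted(SPELLED_NUMBERS))
_SP_SEQ = rf"(?:{_SP})(?:\s+(?:to|or|and)\s+(?:{_SP}))?"
_PERIOD_WORDS = r"(?:days?|weeks?|months?|years?|yrs?)"

QUIT_VERBS = frozenset({"quit", "quits", "stop", "stops", "stopped", "discontinued",
                        "until", "since"})
_LAST_HEADS = frozenset({"use", "used", "drink", "cigarette", "dose", "one"})
_PERIOD_LEADS = frozenset({"for", "times", "time", "x", "×"})


def _unit_re(lex: LexiconSet) -> str:
    units = sorted(lex.unit_nouns, key=len, reverse=True)
    return "(?:" + "|".join(re.escape(u) for u in units) + ")"


def _spans_from_regex(
    pattern: re.Pattern, text: str, offset: int, kind: AttributeKind, scan: SourceScan | None
) -> list[AttributeSpan]:
    out = []
    for m in pattern.finditer(text):
        out.append(
            AttributeSpan(
                kind=kind,
                text=m.group(1),
                char_start=offset + m.start(1),
                char_end=offset + m.end(1),
                source_scan=scan,
            )
        )
    return out


def extract_amount(
    sentence: Sentence,
    chunks: list[Chunk],
    lex: LexiconSet,
    record_text: str,
    positive_mentions: list[Mention],
) -> list[AttributeSpan]:
    """Three-scan amount extraction; the first non-empty scan wins."""
    text = sentence.text_of(record_text)
    off = sentence.char_start
    unit = _unit_re(lex)

    scan1 = re.compile(rf"\b({_AMT_NUM}\s+{unit})\b", re.IGNORECASE)
    spans = _spans_from_regex(scan1, text, off, AttributeKind.AMOUNT, SourceScan.REGEX)
    if spans:
        return spans

    scan2 = re.compile(
        rf"\b((?:up\s+to\s+)?{_SP_SEQ}\s+{unit})\b", re.IGNORECASE
    )
    spans = _spans_from_regex(scan2, text, off, AttributeKind.AMOUNT, SourceScan.SYNTACTIC)
    if spans:
        return spans

    # lexical scan: descriptor in (or adjacent to) the keyword's chunk
    out = []
    mention_chunks = set()
    for m in positive_mentions:
        c = chunk_of(chunks, m.token_span[0])
        idx = chunks.index(c)
        mention_chunks.update(range(max(0, idx - 1), min(len(chunks), idx + 2)))
    for ci in sorted(mention_chunks):
        c = chunks[ci]
        for k in range(c.token_span[0], c.token_span[1]):
            t = sentence.tokens[k]
            if t.norm in lex.amount_lexical_terms:
                out.append(
                    AttributeSpan(
                        kind=AttributeKind.AMOUNT,
                        text=t.text,
                        char_start=t.char_start,
                        char_end=t.char_end,
                        source_scan=SourceScan.LEXICAL,
                    )
                )
    return out


def extract_type(
    sentence: Sentence, lex: LexiconSet, record_text: str, substance: Substance
) -> list[AttributeSpan]:
    """Every match of the substance's type sub-lexicon becomes a TYPE span."""
    out = []
    for words, t_start, t_end in match_term_spans(sentence, lex.type_terms[substance]):
        start = sentence.tokens[t_start].char_start
        end = sentence.tokens[t_end - 1].char_end
        out.append(
            AttributeSpan(
                kind=AttributeKind.TYPE,
                text=record_text[start:end],
                char_start=start,
                char_end=end,
                substance=substance,
            )
        )
    return out


def extract_frequency(
    sentence: Sentence,
    amount_spans: list[AttributeSpan],
    lex: LexiconSet,
    record_text: str,
) -> list[AttributeSpan]:
    """Pattern pass (amount/"times" + connector + period word), lexical fallback."""
    text = sentence.text_of(record_text)
    off = sentence.char_start
    out: list[AttributeSpan] = []

    # "times" head, optionally with its own amount value: "one to two times a month"
    times_pat = re.compile(
        rf"\b((?:(?:{_SP_SEQ}|{_AMT_NUM})\s+)?times?\s+(?:(?:per|a|every)\s+|[/-]\s*){_PERIOD_WORDS})\b",
        re.IGNORECASE,
    )
    out.extend(_spans_from_regex(times_pat, text, off, AttributeKind.FREQUENCY, SourceScan.REGEX))

    # connector + period word immediately following an extracted amount: "2 ppd per day"
    tail_pat = re.compile(
        rf"\s*((?:per|a|every)\s+{_PERIOD_WORDS}|[/-]\s*{_PERIOD_WORDS})\b", re.IGNORECASE
    )
    for a in amount_spans:
        m = tail_pat.match(text, a.char_end - off)
        if m:
            out.append(
                AttributeSpan(
                    kind=AttributeKind.FREQUENCY,
                    text=m.group(1),
                    char_start=off + m.start(1),
                    char_end=off + m.end(1),
                    source_scan=SourceScan.REGEX,
                )
            )
    if out:
        return out

    for t in sentence.tokens:
        if t.is_word and t.norm in lex.frequency_lexical_terms:
            out.append(
                AttributeSpan(
                    kind=AttributeKind.FREQUENCY,
                    text=t.text,
                    char_start=t.char_start,
                    char_end=t.char_end,
                    source_scan=SourceScan.LEXICAL,
                )
            )
    return out


def _cd_phrase_span(sentence: Sentence, start_tok: int) -> tuple[int, int] | None:
    """Span of a cardinal phrase starting at token *start_tok*:
    the CD plus an optional trailing "<period word> ago" / "ago"."""
    toks = sentence.tokens
    t = toks[start_tok]
    if t.pos_tag != "CD":
        return None
    end_tok = start_tok
    j = start_tok + 1
    if j < len(toks) and re.fullmatch(_PERIOD_WORDS, toks[j].norm):
        if j + 1 < len(toks) and toks[j + 1].norm == "ago":
            end_tok = j + 1
    elif j < len(toks) and toks[j].norm == "ago":
        end_tok = j
    return (t.char_start, toks[end_tok].char_end)


def extract_quit_and_period(
    sentence: Sentence, lex: LexiconSet, record_text: str
) -> list[AttributeSpan]:
    toks = sentence.tokens
    quit_spans: list[AttributeSpan] = []
    period_spans: list[AttributeSpan] = []

    # quit verbs followed (within 3 word tokens, not across a period
    # connector) by a cardinal
    for i, t in enumerate(toks):
        is_quit_verb = t.norm in QUIT_VERBS
        if t.norm == "last":
            nxt = [w for w in toks[i + 1:] if w.is_word]
            is_quit_verb = bool(nxt) and nxt[0].norm in _LAST_HEADS
        if not is_quit_verb:
            continue
        steps = 0
        for j in range(i + 1, len(toks)):
            if not toks[j].is_word:
                continue
            steps += 1
            if steps > 3 or toks[j].norm in _PERIOD_LEADS:
                break
            if toks[j].pos_tag == "CD":
                span = _cd_phrase_span(sentence, j)
                if span:
                    quit_spans.append(
                        AttributeSpan(
                            kind=AttributeKind.QUIT_TIME,
                            text=record_text[span[0]:span[1]],
                            char_start=span[0],
                            char_end=span[1],
                        )
                    )
                break

    # bare "<CD> [period word] ago"
    for i, t in enumerate(toks):
        if t.pos_tag != "CD":
            continue
        span = _cd_phrase_span(sentence, i)
        if span and record_text[span[0]:span[1]].lower().endswith("ago"):
            quit_spans.append(
                AttributeSpan(
                    kind=AttributeKind.QUIT_TIME,
                    text=record_text[span[0]:span[1]],
                    char_start=span[0],
                    char_end=span[1],
                )
            )

    # period: for/times/×/x + cardinal (range allowed) + period word
    n = len(toks)
    for i, t in enumerate(toks):
        if t.norm not in _PERIOD_LEADS:
            continue
        j = i + 1
        if j < n and toks[j].pos_tag == "CD":
            k = j
            if k + 2 < n and toks[k + 1].norm in {"to", "-", "–"} and toks[k + 2].pos_tag == "CD":
                k = k + 2
            if k + 1 < n and re.fullmatch(_PERIOD_WORDS, toks[k + 1].norm):
                start, end = t.char_start, toks[k + 1].char_end
                period_spans.append(
                    AttributeSpan(
                        kind=AttributeKind.PERIOD,
                        text=record_text[start:end],
                        char_start=start,
                        char_end=end,
                    )
                )

    # de-duplicate and resolve double claims on the same cardinal:
    # quit-time wins when a quit verb or "ago" backed it, else period stands
    quit_spans = list(dict.fromkeys(quit_spans))
    period_spans = [
        p
        for p in period_spans
        if not any(q.char_start < p.char_end and p.char_start < q.char_end for q in quit_spans)
    ]
    return quit_spans + period_spans


def assign_attributes(
    sentence: Sentence,
    spans: list[AttributeSpan],
    positive_mentions: list[Mention],
    inherited: tuple[Substance, ...] = (),
) -> list[AttributeSpan]:
    """Attach each span to the adjacent positive mention's substance.

    Ties and ambiguity resolve toward the nearest prior (leftward) mention.
    Sentences linked by the orphan-quit rule have no mention of their own and
    inherit the linked substances instead. Unassignable spans are dropped.
    """
    if not positive_mentions and not inherited:
        return []
    wpos = word_positions(sentence)
    toks = sentence.tokens
    out = []
    for span in spans:
        if span.substance is not None:  # TYPE spans are born assigned
            out.append(span)
            continue
        if not positive_mentions:
            for sub in inherited:
                out.append(AttributeSpan(
                    kind=span.kind, text=span.text, char_start=span.char_start,
                    char_end=span.char_end, substance=sub, source_scan=span.source_scan,
                ))
            continue
        anchor = next(
            (t for t in toks if t.is_word and t.char_end > span.char_start), toks[0]
        )

        def key(m: Mention):
            k_lo = wpos[toks[m.token_span[0]].index]
            k_hi = wpos[toks[m.token_span[1] - 1].index]
            a = wpos.get(anchor.index, k_lo)
            if k_hi <= a:
                return (a - k_hi, 0)  # prior mention wins ties
            return (k_lo - a, 1)

        winner = min(positive_mentions, key=key)
        out.append(AttributeSpan(
            kind=span.kind, text=span.text, char_start=span.char_start,
            char_end=span.char_end, substance=winner.substance,
            source_scan=span.source_scan,
        ))
    return out
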