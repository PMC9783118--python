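"""Sentence segmentation, tokenization, section detection, shallow chunking.

The tagging is deliberately minimal: the downstream syntactic patterns only
need to distinguish cardinal values (tag ``CD``: digits, numeric ranges,
fractions, date-like tokens, spelled-out numerals) from everything else.
Tokenization keeps clinically meaningful units whole: hyphenated compounds
("ex-smoker"), sign-prefixed assertions ("-tob", "+etho"), and numeric
ranges ("1-2", "3–4").
"""

from __future__ import annotations

import re

from .lexicons import LexiconSet
from .model import Chunk, Record, Section, Sentence, Token

SPELLED_NUMBERS = frozenset(
    """one two three four five six seven eight nine ten eleven twelve thirteen
    fourteen fifteen sixteen seventeen eighteen nineteen twenty thirty forty
    fifty sixty seventy eighty ninety hundred half""".split()
)

_TOKEN_RE = re.compile(
    r"""
    \d+/\d+(?:/\d+)?                      # date (3/2/05) or fraction (1/2)
    | \d+(?:\.\d+)?[-–]\d+(?:\.\d+)?      # numeric range, single CD token
    | \d+(?:\.\d+)?                       # plain number
    | [+-][A-Za-z][A-Za-z'-]*             # sign-prefixed word (-tob, +etho)
    | [A-Za-z][A-Za-z']*(?:-[A-Za-z][A-Za-z']*)*   # word / hyphenated compound
    | \S                                  # any other single character
    """,
    re.VERBOSE,
)

_ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "st", "jr", "sr", "vs", "prof", "pt", "approx", "etc", "eg", "ie"}
)


def _is_cd(text: str) -> bool:
    t = text.lower()
    return bool(re.match(r"^\d", t)) or t in SPELLED_NUMBERS


def _tokenize_span(text: str, start: int, end: int) -> list[Token]:
    tokens = []
    for i, m in enumerate(_TOKEN_RE.finditer(text, start, end)):
        tok_text = m.group()
        is_word = any(ch.isalnum() for ch in tok_text)
        tag = "CD" if _is_cd(tok_text) else ("W" if is_word else "P")
        tokens.append(
            Token(
                text=tok_text,
                char_start=m.start(),
                char_end=m.end(),
                index=i,
                is_word=is_word,
                pos_tag=tag,
            )
        )
    return tokens


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    """Split on ., !, ? and newlines; abbreviations and decimals do not split."""
    boundaries = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            boundaries.append((i, i + 1))
        elif c in ".!?":
            if c == "." and 0 < i < n - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
                i += 1
                continue
            if c == ".":
                j = i - 1
                while j >= 0 and (text[j].isalnum() or text[j] == "."):
                    j -= 1
                prev_word = text[j + 1:i].lower().rstrip(".")
                if prev_word in _ABBREVIATIONS or (len(prev_word) == 1 and prev_word.isalpha()):
                    i += 1
                    continue
            j = i + 1
            while j < n and text[j] in ".!?":
                j += 1
            boundaries.append((i, j))
            i = j
            continue
        i += 1

    spans = []
    start = 0
    for b_start, b_end in boundaries:
        seg_end = b_end if text[b_start] != "\n" else b_start
        if text[start:seg_end].strip():
            spans.append((start, seg_end))
        start = b_end
    if text[start:].strip():
        spans.append((start, n))

    # trim surrounding whitespace so spans slice cleanly to visible text
    trimmed = []
    for s, e in spans:
        seg = text[s:e]
        s2 = s + (len(seg) - len(seg.lstrip()))
        e2 = e - (len(seg) - len(seg.rstrip()))
        if s2 < e2:
            trimmed.append((s2, e2))
    return trimmed


_HEADER_RE = re.compile(r"^[ \t]*([A-Za-z][A-Za-z /&-]{0,58}?)[ \t]*:", re.MULTILINE)


def detect_sections(record: Record, lex: LexiconSet) -> list[Section]:
    """Find section headers at line starts and partition the record by them.

    All-caps headers always match; mixed-case headers match only when listed
    in the shipped header inventory. Text before the first header becomes a
    PREAMBLE section.
    """
    headers = []
    for m in _HEADER_RE.finditer(record.text):
        name = m.group(1).strip()
        if not (2 <= len(name) <= 60):
            continue
        known = name.lower() in lex.section_headers
        all_caps = name.upper() == name
        if not (all_caps or known):
            continue
        canonical = lex.section_headers.get(
            name.lower(), re.sub(r"[^A-Z0-9]+", "_", name.upper()).strip("_")
        )
        headers.append((m.start(1), m.end(), name, canonical))

    sections: list[Section] = []
    if not headers or headers[0][0] > 0:
        end = headers[0][0] if headers else len(record.text)
        sections.append(Section("", "PREAMBLE", 0, end))
    for i, (h_start, h_end, name, canonical) in enumerate(headers):
        sec_end = headers[i + 1][0] if i + 1 < len(headers) else len(record.text)
        sections.append(
            Section(
                header_text=name,
                canonical_name=canonical,
                char_start=h_start,
                char_end=sec_end,
                header_char_start=h_start,
                header_char_end=h_end,
            )
        )
    return sections


def segment_and_tokenize(record: Record, sections: list[Section] | None = None) -> list[Sentence]:
    """Split the record into tokenized sentences; tag each with its section."""
    sentences = []
    for idx, (s, e) in enumerate(_sentence_spans(record.text)):
        sent = Sentence(
            index=idx, char_start=s, char_end=e, tokens=_tokenize_span(record.text, s, e)
        )
        if sections:
            for sec in sections:
                if sec.char_start <= s < sec.char_end:
                    sent.section = sec.canonical_name
        sentences.append(sent)
    return sentences


#: function words that terminate a noun-phrase run (verbs, prepositions,
#: adverbs, pronouns); deliberately small — everything unlisted is noun-ish,
#: which suits the recall-oriented patterns built on top of the chunks.
CHUNK_BREAKERS = frozenset(
    """is are was were be been being am has have had does do did not no never
    none denies denied denying admits admitted reports reported notes noted
    states stated says said quit quits drinks drank smokes smoked uses used
    using consumes consumed wants wanted continues continued stop stops
    stopped discontinued advise advised of with without per at on from by
    about after before during since until ago for when while if then than
    daily nightly occasionally rarely socially currently approximately
    or nor but he she they it we you i his her their its who whom that which
    this these those should would could will shall can may might must
    there here also only very more most much still
    """.split()
)

_DETERMINERS = frozenset({"a", "an", "the"})
_CD_BRIDGES = frozenset({"to", "and", "or"})


def shallow_chunk(sentence: Sentence) -> list[Chunk]:
    """Greedy noun-phrase chunking over the minimal tag set.

    Maximal runs of determiner/CD/noun-ish tokens (with "to"/"and" admitted
    between two CDs, as in "2 and 1/2 to 3 packs") ending in a noun or CD
    form NP chunks; every other token is a singleton chunk. The result
    partitions the sentence's tokens.
    """
    toks = sentence.tokens
    n = len(toks)

    def in_np(i: int, run_open: bool) -> bool:
        t = toks[i]
        low = t.norm
        if not t.is_word:
            return False
        if t.pos_tag == "CD":
            return True
        if low in _CD_BRIDGES:
            prev_cd = i > 0 and toks[i - 1].pos_tag == "CD"
            next_cd = i + 1 < n and toks[i + 1].pos_tag == "CD"
            return run_open and prev_cd and next_cd
        if low in CHUNK_BREAKERS:
            return False
        return True  # noun-ish by default (includes determiners/adjectives)

    chunks: list[Chunk] = []
    i = 0
    while i < n:
        if not in_np(i, run_open=False):
            chunks.append(Chunk("O", (i, i + 1)))
            i += 1
            continue
        j = i
        while j < n and in_np(j, run_open=(j > i)):
            j += 1
        # a chunk must end in a noun or CD: shed trailing determiners/bridges
        end = j
        while end > i and (
            toks[end - 1].norm in _DETERMINERS or toks[end - 1].norm in _CD_BRIDGES
        ):
            end -= 1
        if end == i:
            end = i + 1
            chunks.append(Chunk("O", (i, end)))
        else:
            chunks.append(Chunk("NP", (i, end)))
        for k in range(end, j):
            chunks.append(Chunk("O", (k, k + 1)))
        i = j

    return chunks


def chunk_of(chunks: list[Chunk], token_index: int) -> Chunk:
    for c in chunks:
        if c.token_span[0] <= token_index < c.token_span[1]:
            return c
    raise ValueError(f"token index {token_index} not covered by chunks")


def word_positions(sentence: Sentence) -> dict[int, int]:
    """Map token index -> rank among word tokens (for word-window distances)."""
    pos = {}
    rank = 0
    for t in sentence.tokens:
        if t.is_word:
            pos[t.index] = rank
            rank += 1
    return pos


def word_distance(sentence: Sentence, i: int, j: int) -> int:
    """Word-token distance between two word tokens of one sentence."""
    pos = word_positions(sentence)
    return abs(pos[i] - pos[j])
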