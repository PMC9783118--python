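"""End-to-end orchestration of the four extraction stages.

Stage order is strict: relevance gating (Unknown records are discarded),
negation (NONE substances never reach the temporal stage), temporal
classification, then attribute extraction for PAST/CURRENT substances only.
Document granularity emits one status per substance per record; sentence
granularity additionally emits per-sentence statuses whose OR-aggregation
reproduces the document status.
"""

from __future__ import annotations

import logging

from .attributes import (
    assign_attributes,
    extract_amount,
    extract_frequency,
    extract_quit_and_period,
    extract_type,
)
from .lexicons import LexiconSet, load_lexicons
from .model import (
    SUBSTANCES,
    Granularity,
    Mention,
    Record,
    RecordResult,
    Status,
    Substance,
    SubstanceResult,
)
from .negation import NegationConfig, Polarity, aggregate_polarity, polarity_of_mention
from .preprocess import detect_sections, segment_and_tokenize, shallow_chunk
from .relevance import attach_orphan_quit, classify_known, find_mentions
from .temporal import current_indicator, temporal_status

logger = logging.getLogger("substex")


def _unknown_result(record: Record, granularity: Granularity) -> RecordResult:
    return RecordResult(
        record_id=record.record_id,
        results={
            s: SubstanceResult(substance=s, status=Status.UNKNOWN) for s in SUBSTANCES
        },
        granularity=granularity,
        per_sentence={} if granularity is Granularity.SENTENCE else None,
        discarded=True,
    )


def run_record(
    record: Record,
    lex: LexiconSet,
    cfg: NegationConfig | None = None,
    granularity: Granularity = Granularity.DOCUMENT,
) -> RecordResult:
    cfg = cfg or NegationConfig()

    sections = detect_sections(record, lex)
    sentences = segment_and_tokenize(record, sections)
    chunks = {s.index: shallow_chunk(s) for s in sentences}
    mentions = find_mentions(sentences, lex, record.text, chunks)
    quit_links = attach_orphan_quit(sentences, mentions)
    known = classify_known(mentions)

    if not any(known.values()):
        logger.info("record %s discarded: no active substance mentions", record.record_id)
        return _unknown_result(record, granularity)

    sent_by_idx = {s.index: s for s in sentences}
    active_by_sentence: dict[int, list[Mention]] = {}
    for m in mentions:
        if m.active:
            active_by_sentence.setdefault(m.sentence_index, []).append(m)

    decisions = []
    for s_idx, sent_mentions in active_by_sentence.items():
        sent = sent_by_idx[s_idx]
        for m in sent_mentions:
            d = polarity_of_mention(m, sent, sections, lex, cfg, sent_mentions)
            logger.debug(
                "record %s sent %d %s %r: %s (%s)",
                record.record_id, s_idx, m.substance.json_key, m.keyword,
                d.polarity.value, d.rule_fired.value,
            )
            decisions.append(d)

    by_substance: dict[Substance, list] = {s: [] for s in SUBSTANCES}
    for d in decisions:
        by_substance[d.mention.substance].append(d)

    aggregate = {}
    for sub in SUBSTANCES:
        if by_substance[sub]:
            aggregate[sub] = aggregate_polarity(by_substance[sub], extended=cfg.extensions)

    positive_decisions = [
        d
        for d in decisions
        if d.polarity is Polarity.POSITIVE
        and aggregate.get(d.mention.substance) is Polarity.POSITIVE
    ]
    positive_subs = {d.mention.substance for d in positive_decisions}
    sub_quit_links = [
        l
        for l in quit_links
        if any(s in positive_subs for s in l.substances)
    ]
    doc_temporal, mention_status = temporal_status(
        sentences, chunks, positive_decisions, sub_quit_links, lex
    )

    status: dict[Substance, Status] = {}
    for sub in SUBSTANCES:
        if not known[sub]:
            status[sub] = Status.UNKNOWN
        elif aggregate.get(sub) is Polarity.NEGATIVE:
            status[sub] = Status.NONE
        else:
            status[sub] = doc_temporal.get(sub, Status.CURRENT)

    # stage 4 on sentences holding positive mentions of PAST/CURRENT substances
    attrs_by_sub: dict[Substance, list] = {s: [] for s in SUBSTANCES}
    extractable = {s for s in SUBSTANCES if status[s] in (Status.PAST, Status.CURRENT)}
    pos_mentions_by_sentence: dict[int, list[Mention]] = {}
    for d in positive_decisions:
        if d.mention.substance in extractable:
            pos_mentions_by_sentence.setdefault(d.mention.sentence_index, []).append(d.mention)

    for s_idx, pos_mentions in pos_mentions_by_sentence.items():
        sent = sent_by_idx[s_idx]
        spans = []
        amounts = extract_amount(sent, chunks[s_idx], lex, record.text, pos_mentions)
        spans.extend(amounts)
        spans.extend(extract_frequency(sent, amounts, lex, record.text))
        spans.extend(extract_quit_and_period(sent, lex, record.text))
        for sub in {m.substance for m in pos_mentions}:
            spans.extend(extract_type(sent, lex, record.text, sub))
        for span in assign_attributes(sent, spans, pos_mentions):
            if span.substance in extractable:
                attrs_by_sub[span.substance].append(span)

    for link in sub_quit_links:
        inherited = tuple(s for s in link.substances if s in extractable)
        if not inherited:
            continue
        sent = sent_by_idx[link.quit_sentence]
        spans = []
        amounts = extract_amount(sent, chunks[link.quit_sentence], lex, record.text, [])
        spans.extend(amounts)
        spans.extend(extract_frequency(sent, amounts, lex, record.text))
        spans.extend(extract_quit_and_period(sent, lex, record.text))
        for sub in inherited:
            spans.extend(extract_type(sent, lex, record.text, sub))
        for span in assign_attributes(sent, spans, [], inherited):
            if span.substance in extractable:
                attrs_by_sub[span.substance].append(span)

    evidence: dict[Substance, set[int]] = {s: set() for s in SUBSTANCES}
    for m in mentions:
        if m.active:
            evidence[m.substance].add(m.sentence_index)
    for link in quit_links:
        for sub in link.substances:
            evidence[sub].add(link.quit_sentence)

    results = {}
    for sub in SUBSTANCES:
        results[sub] = SubstanceResult(
            substance=sub,
            status=status[sub],
            attributes=sorted(
                attrs_by_sub[sub], key=lambda a: (a.char_start, a.char_end, a.kind.value)
            )
            if status[sub] in (Status.PAST, Status.CURRENT)
            else [],
            evidence_sentences=sorted(evidence[sub]) if status[sub] is not Status.UNKNOWN else [],
        )

    per_sentence = None
    if granularity is Granularity.SENTENCE:
        per_sentence = {}
        linked_subs_by_sentence: dict[int, tuple] = {
            l.quit_sentence: l.substances for l in sub_quit_links
        }
        for sent in sentences:
            statuses = {}
            for sub in SUBSTANCES:
                sent_decisions = [
                    d
                    for d in decisions
                    if d.mention.sentence_index == sent.index and d.mention.substance is sub
                ]
                if sent_decisions:
                    agg = aggregate_polarity(sent_decisions, extended=cfg.extensions)
                    if agg is Polarity.NEGATIVE or status[sub] is Status.NONE:
                        statuses[sub] = Status.NONE
                    else:
                        m_statuses = [
                            mention_status.get(
                                (sent.index, d.mention.token_span[0]), Status.CURRENT
                            )
                            for d in sent_decisions
                            if d.polarity is Polarity.POSITIVE
                        ]
                        statuses[sub] = (
                            Status.CURRENT
                            if Status.CURRENT in m_statuses or not m_statuses
                            else Status.PAST
                        )
                elif sub in linked_subs_by_sentence.get(sent.index, ()):
                    statuses[sub] = (
                        Status.CURRENT
                        if current_indicator(sent, sub, lex)
                        else Status.PAST
                    )
                else:
                    statuses[sub] = Status.UNKNOWN
            per_sentence[sent.index] = statuses

    return RecordResult(
        record_id=record.record_id,
        results=results,
        granularity=granularity,
        per_sentence=per_sentence,
    )


def run_pipeline(
    records: list[Record],
    lex: LexiconSet | None = None,
    cfg: NegationConfig | None = None,
    granularity: Granularity = Granularity.DOCUMENT,
) -> list[RecordResult]:
    lex = lex or load_lexicons()
    return [run_record(r, lex, cfg, granularity) for r in records]


def active_mention_spans(record: Record, lex: LexiconSet) -> list[tuple[Substance, int, int]]:
    """Character spans of active mentions (status evidence for BRAT output)."""
    sections = detect_sections(record, lex)
    sentences = segment_and_tokenize(record, sections)
    chunks = {s.index: shallow_chunk(s) for s in sentences}
    mentions = find_mentions(sentences, lex, record.text, chunks)
    return [(m.substance, m.char_start, m.char_end) for m in mentions if m.active]
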