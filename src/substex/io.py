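"""Readers and writers: raw record corpora, JSON-lines results, BRAT standoff.

JSON-lines schema (one object per record, keys in fixed order)::

    {"record_id": ..., "granularity": "DOCUMENT"|"SENTENCE",
     "smoking"|"alcohol"|"drugs": {
         "status": "UNKNOWN"|"NONE"|"PAST"|"CURRENT",
         "evidence_sentences": [int, ...],
         "attributes": [{"kind", "text", "start", "end"}, ...]},
     "sentences": [{"index", "smoking", "alcohol", "drugs"}, ...]}  # SENTENCE mode
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .model import (
    SUBSTANCES,
    AttributeKind,
    AttributeSpan,
    EmptyCorpusError,
    Granularity,
    IntegrityError,
    Record,
    RecordResult,
    Status,
    Substance,
    SubstanceResult,
)

#: default separator for DELIMITED corpora: a line of 10 or more asterisks
DEFAULT_SEPARATOR = r"^\*{10,}\s*$"


def read_records(
    path: str | Path,
    layout: str = "ONE_FILE_PER_RECORD",
    separator: str = DEFAULT_SEPARATOR,
) -> list[Record]:
    """Read a corpus of plain-text clinical records.

    ``ONE_FILE_PER_RECORD``: every ``*.txt`` file under *path* (or *path*
    itself if it is a file) is one record, ordered lexicographically by
    filename. ``DELIMITED``: *path* is one file whose records are separated
    by lines matching *separator*.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"corpus path does not exist: {path}")
    records: list[Record] = []
    if layout == "ONE_FILE_PER_RECORD":
        files = [path] if path.is_file() else sorted(path.glob("*.txt"))
        for f in files:
            try:
                text = f.read_text(encoding="utf-8")
            except OSError as exc:
                raise IOError(f"unreadable record file: {f}") from exc
            records.append(Record(record_id=f.stem, text=text))
    elif layout == "DELIMITED":
        try:
            raw = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise IOError(f"unreadable corpus file: {path}") from exc
        sep = re.compile(separator, re.MULTILINE)
        cursor = 0
        blocks = []
        for m in sep.finditer(raw):
            blocks.append(raw[cursor:m.start()])
            cursor = m.end()
        blocks.append(raw[cursor:])
        for i, block in enumerate(b for b in blocks if b.strip()):
            records.append(Record(record_id=f"{path.stem}#{i}", text=block))
    else:
        raise ValueError(f"unknown layout: {layout}")
    if not records:
        raise EmptyCorpusError(f"no records found under {path}")
    return records


def _substance_obj(res: SubstanceResult) -> dict:
    return {
        "status": res.status.value,
        "evidence_sentences": list(res.evidence_sentences),
        "attributes": [
            {"kind": a.kind.value, "text": a.text, "start": a.char_start, "end": a.char_end}
            for a in res.attributes
        ],
    }


def result_to_obj(result: RecordResult) -> dict:
    obj = {"record_id": result.record_id, "granularity": result.granularity.value}
    for sub in SUBSTANCES:
        obj[sub.json_key] = _substance_obj(result.results[sub])
    if result.granularity is Granularity.SENTENCE and result.per_sentence is not None:
        obj["sentences"] = [
            {"index": idx, **{s.json_key: statuses[s].value for s in SUBSTANCES}}
            for idx, statuses in sorted(result.per_sentence.items())
        ]
    return obj


def obj_to_result(obj: dict) -> RecordResult:
    results = {}
    for sub in SUBSTANCES:
        o = obj[sub.json_key]
        results[sub] = SubstanceResult(
            substance=sub,
            status=Status(o["status"]),
            attributes=[
                AttributeSpan(
                    kind=AttributeKind(a["kind"]),
                    text=a["text"],
                    char_start=a["start"],
                    char_end=a["end"],
                    substance=sub,
                )
                for a in o["attributes"]
            ],
            evidence_sentences=list(o["evidence_sentences"]),
        )
    granularity = Granularity(obj["granularity"])
    per_sentence = None
    if "sentences" in obj:
        per_sentence = {
            s["index"]: {sub: Status(s[sub.json_key]) for sub in SUBSTANCES}
            for s in obj["sentences"]
        }
    return RecordResult(
        record_id=obj["record_id"],
        results=results,
        granularity=granularity,
        per_sentence=per_sentence,
    )


def write_results_jsonl(results: list[RecordResult], path: str | Path) -> None:
    if not results:
        raise ValueError("results must be non-empty")
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8") as fh:
            for r in results:
                fh.write(json.dumps(result_to_obj(r)) + "\n")
    except OSError as exc:
        raise IOError(f"unwritable results path: {path}") from exc


def read_results_jsonl(path: str | Path) -> list[RecordResult]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(obj_to_result(json.loads(line)))
    return out


def write_brat(record: Record, result: RecordResult, path: str | Path,
               mention_spans: list[tuple[Substance, int, int]] | None = None) -> None:
    """Write a BRAT standoff ``.ann`` file for one record's result.

    One ``T<n>`` line per attribute span (label ``Smoking_Amount`` style) and
    one per status-evidence keyword span (label ``Smoking_Status:<value>``).
    Refuses to write if any span does not slice cleanly from the record text.
    """
    lines = []
    n = 0
    names = {Substance.SMOKING: "Smoking", Substance.ALCOHOL: "Alcohol", Substance.DRUG: "Drug"}
    for sub, start, end in mention_spans or []:
        status = result.results[sub].status
        if status is Status.UNKNOWN:
            continue
        text = record.text[start:end]
        n += 1
        lines.append(f"T{n}\t{names[sub]}_Status:{status.value} {start} {end}\t{text}")
    for sub in SUBSTANCES:
        for a in result.results[sub].attributes:
            a.validate_against(record.text)
            n += 1
            kind = a.kind.value.title().replace("_", "")
            lines.append(f"T{n}\t{names[sub]}_{kind} {a.char_start} {a.char_end}\t{a.text}")
    Path(path).write_text("".join(l + "\n" for l in lines), encoding="utf-8")
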