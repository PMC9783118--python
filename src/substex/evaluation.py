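"""Per-class sensitivity, precision and F1 for statuses and attribute spans.

Sen_c = TP_c / (TP_c + FN_c), Pre_c = TP_c / (TP_c + FP_c),
F1_c = 2·Pre·Sen / (Pre + Sen). A class absent from both gold and
prediction reports ``None`` rather than zero; undefined ratios (zero
denominators) are also ``None``, with a diagnostic. Macro averages run
over the classes present in gold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence


@dataclass
class ClassMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    diagnostics: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> Optional[float]:
        if self.tp + self.fn == 0:
            return None
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> Optional[float]:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)

    @property
    def f1(self) -> Optional[float]:
        p, s = self.precision, self.sensitivity
        if p is None or s is None or p + s == 0:
            return None
        return 2 * p * s / (p + s)

    def as_dict(self) -> dict:
        return {"Sen": self.sensitivity, "Pre": self.precision, "F1": self.f1,
                "TP": self.tp, "FP": self.fp, "FN": self.fn}


def score(gold: Sequence[Hashable], pred: Sequence[Hashable]) -> dict:
    """Per-class and macro Sen/Pre/F1 over aligned label sequences."""
    if len(gold) != len(pred):
        raise ValueError(f"gold ({len(gold)}) and pred ({len(pred)}) length mismatch")
    classes = sorted({str(c) for c in gold} | {str(c) for c in pred})
    per_class: dict[str, ClassMetrics] = {}
    for c in classes:
        m = ClassMetrics()
        for g, p in zip(gold, pred):
            g, p = str(g), str(p)
            if g == c and p == c:
                m.tp += 1
            elif g != c and p == c:
                m.fp += 1
            elif g == c and p != c:
                m.fn += 1
        if m.sensitivity is None:
            m.diagnostics.append(f"class {c}: sensitivity undefined (no gold instances)")
        if m.precision is None:
            m.diagnostics.append(f"class {c}: precision undefined (no predictions)")
        per_class[c] = m

    gold_classes = [c for c in classes if any(str(g) == c for g in gold)]
    macro = {}
    for name in ("Sen", "Pre", "F1"):
        vals = [per_class[c].as_dict()[name] for c in gold_classes]
        vals = [v for v in vals if v is not None]
        macro[name] = sum(vals) / len(vals) if vals else None
    return {
        "per_class": {c: per_class[c].as_dict() for c in classes},
        "macro": macro,
        "diagnostics": [d for c in classes for d in per_class[c].diagnostics],
    }


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def score_spans(
    gold: Iterable[tuple],
    pred: Iterable[tuple],
    lenient: bool = False,
) -> ClassMetrics:
    """Span-set Sen/Pre/F1.

    Each item is ``(unit_id, char_start, char_end)`` (the unit id typically
    packs record id, substance and attribute kind). Exact matching compares
    full tuples; lenient matching greedily pairs spans of the same unit that
    overlap in character range.
    """
    gold, pred = list(gold), list(pred)
    m = ClassMetrics()
    if not lenient:
        g_count, p_count = Counter(gold), Counter(pred)
        m.tp = sum(min(g_count[k], p_count[k]) for k in g_count)
        m.fp = len(pred) - m.tp
        m.fn = len(gold) - m.tp
        return m
    unmatched_gold = list(gold)
    for p in pred:
        hit = next(
            (
                g
                for g in unmatched_gold
                if g[0] == p[0] and _overlaps((g[1], g[2]), (p[1], p[2]))
            ),
            None,
        )
        if hit is not None:
            unmatched_gold.remove(hit)
            m.tp += 1
        else:
            m.fp += 1
    m.fn = len(unmatched_gold)
    return m


def score_corpus(gold_results, pred_results, lenient: bool = False) -> dict:
    """Score aligned lists of RecordResults: statuses per substance and
    attribute spans per attribute kind (pooled over substances)."""
    from .model import SUBSTANCES, AttributeKind, Status

    gold_by_id = {r.record_id: r for r in gold_results}
    pred_by_id = {r.record_id: r for r in pred_results}
    if set(gold_by_id) != set(pred_by_id):
        raise ValueError("gold and prediction record ids do not match")
    ids = sorted(gold_by_id)

    status_report = {}
    for sub in SUBSTANCES:
        g = [gold_by_id[i].results[sub].status.value for i in ids]
        p = [pred_by_id[i].results[sub].status.value for i in ids]
        status_report[sub.json_key] = score(g, p)

    attr_report = {}
    for kind in AttributeKind:
        def spans(results_by_id):
            out = []
            for i in ids:
                for sub in SUBSTANCES:
                    res = results_by_id[i].results[sub]
                    if res.status not in (Status.PAST, Status.CURRENT):
                        continue
                    for a in res.attributes:
                        if a.kind is kind:
                            out.append(((i, sub.json_key, kind.value), a.char_start, a.char_end))
            return out

        m = score_spans(spans(gold_by_id), spans(pred_by_id), lenient=lenient)
        attr_report[kind.value] = m.as_dict()
    return {"status": status_report, "attributes": attr_report}


def format_report(results: dict[str, dict], fmt: str = "tsv") -> str:
    """Render {group: score()-output} as a TSV table (or leave JSON to callers)."""
    lines = ["group\tclass\tSen\tPre\tF1\tTP\tFP\tFN"]

    def cell(v):
        return "-" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v))

    for group, res in results.items():
        for cls, d in res["per_class"].items():
            lines.append(
                "\t".join(
                    [group, cls] + [cell(d[k]) for k in ("Sen", "Pre", "F1", "TP", "FP", "FN")]
                )
            )
        mac = res["macro"]
        lines.append(
            "\t".join([group, "MACRO", cell(mac["Sen"]), cell(mac["Pre"]), cell(mac["F1"]), "", "", ""])
        )
    return "\n".join(lines)
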