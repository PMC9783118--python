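"""Seeded synthetic discharge-summary generator with gold annotations.

Records emulate the structure of hospital discharge summaries: a preamble,
HISTORY OF PRESENT ILLNESS, ALLERGIES, SOCIAL HISTORY and FOLLOW UP AND
INSTRUCTIONS sections. Substance-use sentences are drawn from a template
bank keyed by the intended gold label; gold statuses and attribute spans
are fixed at template-authoring time. Distractor sentences (misleading
concepts, restricted-section keyword traps, non-alcoholic "drink" phrases,
unqualified "PPD") exercise the suppression rules and contribute no gold
status. The same (spec, seed) always yields a byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    SUBSTANCES,
    AttributeKind,
    AttributeSpan,
    Granularity,
    Record,
    RecordResult,
    Status,
    Substance,
    SubstanceResult,
)

#: uniform mix over the four status classes
UNIFORM_MIX = {
    Status.UNKNOWN: 0.25,
    Status.NONE: 0.25,
    Status.PAST: 0.25,
    Status.CURRENT: 0.25,
}


@dataclass
class GenerationSpec:
    n_records: int = 100
    seed: int = 0
    class_mix: dict[Substance, dict[Status, float]] = field(
        default_factory=lambda: {s: dict(UNIFORM_MIX) for s in SUBSTANCES}
    )
    distractor_rate: float = 0.3
    attribute_rate: float = 0.6  # probability of an attribute-bearing template

    def __post_init__(self) -> None:
        for sub, mix in self.class_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"class mix for {sub.json_key} sums to {total}, not 1")


@dataclass(frozen=True)
class Template:
    """One or more sentences asserting a substance-use status.

    ``attributes`` lists (kind, substring) pairs; each substring must occur
    exactly once in ``text`` and is resolved to character offsets when the
    template is placed into a record. ``rules`` names the pipeline rules the
    template exercises (used by the coverage inventory).
    """

    text: str
    substance: Substance
    status: Status
    attributes: tuple[tuple[AttributeKind, str], ...] = ()
    rules: tuple[str, ...] = ()


S, A, D = Substance.SMOKING, Substance.ALCOHOL, Substance.DRUG
K = AttributeKind

#: templates safe for closed-loop generation: single substance, self-contained
TEMPLATES: dict[tuple[Substance, Status], list[Template]] = {
    (S, Status.CURRENT): [
        Template("He smokes 1 to 2 packs per day.", S, Status.CURRENT,
                 ((K.AMOUNT, "1 to 2 packs"), (K.FREQUENCY, "per day")),
                 ("AMOUNT_REGEX", "FREQ_PATTERN")),
        Template("Smokes 2 ppd.", S, Status.CURRENT,
                 ((K.AMOUNT, "2 ppd"),), ("AMOUNT_REGEX", "PPD_QUALIFIED")),
        Template("He smokes about five packs a week.", S, Status.CURRENT,
                 ((K.AMOUNT, "five packs"), (K.FREQUENCY, "a week")),
                 ("AMOUNT_SYNTACTIC", "FREQ_PATTERN")),
        Template("Patient smokes cigarettes daily.", S, Status.CURRENT,
                 ((K.TYPE, "cigarettes"), (K.FREQUENCY, "daily")),
                 ("TYPE_LEXICON", "FREQ_LEXICAL")),
        Template("Heavy tob use.", S, Status.CURRENT,
                 ((K.AMOUNT, "Heavy"),), ("AMOUNT_LEXICAL",)),
        Template("She is a current smoker.", S, Status.CURRENT),
        Template("Wants to quit smoking.", S, Status.CURRENT,
                 (), ("CURRENT_INDICATOR",)),
    ],
    (S, Status.PAST): [
        Template("He is a former smoker.", S, Status.PAST, (), ("ONE_AFTER",)),
        Template("She is an ex-smoker.", S, Status.PAST, (), ("EX_PREFIX",)),
        Template("He quit smoking in 1994.", S, Status.PAST,
                 ((K.QUIT_TIME, "1994"),),
                 ("ONE_AFTER_ELSE_ALL_BEFORE", "QUIT_TIME")),
        Template("Smoked tobacco until 1990.", S, Status.PAST,
                 ((K.QUIT_TIME, "1990"),), ("ALL_BEFORE", "QUIT_TIME")),
        Template("He smoked 2 packs per day for 30 years but stopped smoking in 1994.",
                 S, Status.PAST,
                 ((K.AMOUNT, "2 packs"), (K.FREQUENCY, "per day"),
                  (K.PERIOD, "for 30 years"), (K.QUIT_TIME, "1994")),
                 ("AMOUNT_REGEX", "FREQ_PATTERN", "PERIOD", "QUIT_TIME",
                  "ONE_AFTER_ELSE_ALL_BEFORE")),
        Template("He smokes cigarettes. Quit 10 years ago.", S, Status.PAST,
                 ((K.TYPE, "cigarettes"), (K.QUIT_TIME, "10 years ago")),
                 ("ORPHAN_QUIT", "TYPE_LEXICON", "QUIT_TIME")),
        Template("Smoking history in the past.", S, Status.PAST, (), ("SAME_CHUNK",)),
    ],
    (S, Status.NONE): [
        Template("He denies tobacco use.", S, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("Nonsmoker.", S, Status.NONE, (), ("SEMANTIC_WORD",)),
        Template("She is a non-smoker.", S, Status.NONE, (), ("SEMANTIC_WORD",)),
        Template("No history of smoking.", S, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("Never smoked.", S, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("-tob.", S, Status.NONE, (), ("SIGN",)),
        Template("Tobacco: None.", S, Status.NONE, (), ("HEADER_NONE",)),
    ],
    (A, Status.CURRENT): [
        Template("She drinks 1-2 beers per week.", A, Status.CURRENT,
                 ((K.AMOUNT, "1-2 beers"), (K.TYPE, "beers"), (K.FREQUENCY, "per week")),
                 ("AMOUNT_REGEX", "TYPE_LEXICON", "FREQ_PATTERN")),
        Template("Drinks alcohol socially.", A, Status.CURRENT),
        Template("He drinks a pint of vodka daily.", A, Status.CURRENT,
                 ((K.TYPE, "vodka"), (K.FREQUENCY, "daily")),
                 ("TYPE_LEXICON", "FREQ_LEXICAL")),
        Template("Drinks one to two times a month.", A, Status.CURRENT,
                 ((K.FREQUENCY, "one to two times a month"),), ("FREQ_PATTERN",)),
        Template("Reports heavy alcohol use.", A, Status.CURRENT,
                 ((K.AMOUNT, "heavy"),), ("AMOUNT_LEXICAL",)),
        Template("Drank beer for 8 to 9 years.", A, Status.CURRENT,
                 ((K.TYPE, "beer"), (K.PERIOD, "for 8 to 9 years")),
                 ("TYPE_LEXICON", "PERIOD")),
    ],
    (A, Status.PAST): [
        Template("He quit drinking 10 years ago.", A, Status.PAST,
                 ((K.QUIT_TIME, "10 years ago"),),
                 ("ONE_AFTER_ELSE_ALL_BEFORE", "QUIT_TIME")),
        Template("Former drinker.", A, Status.PAST, (), ("ONE_AFTER",)),
        Template("She has not drunk alcohol since 1984.", A, Status.PAST,
                 ((K.QUIT_TIME, "1984"),), ("OVERRIDE_TEMPORAL", "QUIT_TIME")),
        Template("Alcohol use in the past.", A, Status.PAST, (), ("SAME_CHUNK",)),
        Template("Quit alcohol 25 years ago.", A, Status.PAST,
                 ((K.QUIT_TIME, "25 years ago"),),
                 ("ONE_AFTER_ELSE_ALL_BEFORE", "QUIT_TIME")),
    ],
    (A, Status.NONE): [
        Template("Denies alcohol use.", A, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("Non-drinker.", A, Status.NONE, (), ("SEMANTIC_WORD",)),
        Template("No etoh.", A, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("Alcohol: None.", A, Status.NONE, (), ("HEADER_NONE",)),
        Template("She does not drink.", A, Status.NONE, (), ("NEGEX_WINDOW",)),
    ],
    (D, Status.CURRENT): [
        Template("Patient uses cocaine daily.", D, Status.CURRENT,
                 ((K.TYPE, "cocaine"), (K.FREQUENCY, "daily")),
                 ("TYPE_LEXICON", "FREQ_LEXICAL")),
        Template("Admits marijuana use.", D, Status.CURRENT,
                 ((K.TYPE, "marijuana"),), ("TYPE_LEXICON",)),
        Template("Current IVDU.", D, Status.CURRENT),
        Template("Used heroin for three years.", D, Status.CURRENT,
                 ((K.TYPE, "heroin"), (K.PERIOD, "for three years")),
                 ("TYPE_LEXICON", "PERIOD")),
    ],
    (D, Status.PAST): [
        Template("Remote drug abuse.", D, Status.PAST, (), ("SAME_CHUNK",)),
        Template("Prior heroin use.", D, Status.PAST,
                 ((K.TYPE, "heroin"),), ("ONE_AFTER", "TYPE_LEXICON")),
        Template("He used cocaine in the past.", D, Status.PAST,
                 ((K.TYPE, "cocaine"),), ("SAME_CHUNK", "TYPE_LEXICON")),
        Template("Last use of heroin seven years ago.", D, Status.PAST,
                 ((K.TYPE, "heroin"), (K.QUIT_TIME, "seven years ago")),
                 ("ONE_AFTER_ELSE_ALL_BEFORE", "QUIT_TIME", "TYPE_LEXICON")),
    ],
    (D, Status.NONE): [
        Template("Denies drug use.", D, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("No illicit drugs.", D, Status.NONE, (), ("NEGEX_WINDOW",)),
        Template("Drug history: None.", D, Status.NONE, (), ("HEADER_NONE",)),
        Template("Never used cocaine.", D, Status.NONE, (), ("NEGEX_WINDOW",)),
    ],
}

#: multi-substance templates that exercise cross-keyword rules; used by the
#: coverage inventory and worked-example tests, not by the random generator
JOINT_TEMPLATES: list[tuple[str, dict[Substance, Status], tuple[str, ...]]] = [
    ("She does not consume alcohol, nor does she smoke.",
     {A: Status.NONE, S: Status.NONE}, ("NOR_EXPANSION", "NEGEX_WINDOW")),
    ("denies smoke, alcohol socially.",
     {S: Status.NONE, A: Status.CURRENT}, ("OVERRIDE_SOCIAL",)),
    ("He is a former smoker, he denies any use of tobacco.",
     {S: Status.PAST}, ("OR_AGGREGATION", "ONE_AFTER")),
    ("History of smoke inhalation.", {}, ("MISLEADING",)),
    ("PPD placed on left forearm.", {}, ("PPD_UNQUALIFIED",)),
    ("He drinks orange juice daily.", {}, ("NON_ALCOHOLIC",)),
    ("Past tobacco use.", {S: Status.PAST}, ("TWO_BEFORE_TWO_AFTER",)),
]

#: documented failure modes of the rule system: gold is the TRUE clinical
#: label; the pipeline is expected to get these WRONG in the stated way
HARD_TEMPLATES: list[tuple[str, dict[Substance, Status], dict[Substance, Status]]] = [
    # text, true gold, expected (wrong) system output
    ("Smoking, no alcohol.",
     {S: Status.CURRENT, A: Status.NONE},
     {S: Status.NONE, A: Status.NONE}),
    ("Abuse of drugs or alcohol were denied.",
     {D: Status.NONE, A: Status.NONE},
     {D: Status.CURRENT, A: Status.NONE}),
    ("History of barbituate abuse.",
     {D: Status.CURRENT},
     {D: Status.UNKNOWN}),
]

DISTRACTORS_HPI = [
    "History of smoke inhalation.",
    "PPD placed on left forearm.",
    "Vaginal pack was placed.",
]
DISTRACTORS_ALLERGIES = [
    "No known drug allergies.",
    "Penicillin causes drug rash.",
]
DISTRACTORS_FOLLOWUP = [
    "You should continue to take adequate food and drink.",
]
DISTRACTORS_BODY = [
    "He drinks orange juice daily.",
]

FILLERS = [
    "Patient admitted with chest pain.",
    "He presented with shortness of breath.",
    "Laboratory values were unremarkable.",
    "The hospital course was uneventful.",
]


def template_inventory() -> list[tuple[str, dict[Substance, Status], tuple[str, ...]]]:
    """Every template with its gold labels and the rule identifiers it exercises."""
    out = []
    for (sub, status), templates in TEMPLATES.items():
        for t in templates:
            out.append((t.text, {sub: status}, t.rules))
    out.extend(JOINT_TEMPLATES)
    return out


def _place(text_parts: list[str], sentence: str) -> int:
    """Append a sentence (space separated) and return its start offset."""
    if text_parts and not text_parts[-1].endswith("\n"):
        text_parts.append(" ")
    offset = sum(len(p) for p in text_parts)
    text_parts.append(sentence)
    return offset


def generate(
    spec: GenerationSpec,
) -> tuple[list[Record], list[RecordResult], list[tuple[str, Substance, AttributeKind, int, int, str]]]:
    """Generate records, gold document-level results, and gold attribute spans.

    Draw order per record (one shared RNG stream): per substance in fixed
    order (smoking, alcohol, drugs): status, then template; then one
    distractor decision per section slot; then filler choice.
    """
    rng = random.Random(spec.seed)
    records: list[Record] = []
    gold_results: list[RecordResult] = []
    gold_spans: list[tuple[str, Substance, AttributeKind, int, int, str]] = []

    for i in range(spec.n_records):
        record_id = f"synthetic-{i:04d}"
        statuses: dict[Substance, Status] = {}
        chosen: dict[Substance, Template | None] = {}
        for sub in SUBSTANCES:
            mix = spec.class_mix[sub]
            classes = sorted(mix, key=lambda s: s.value)
            status = rng.choices(classes, weights=[mix[c] for c in classes])[0]
            statuses[sub] = status
            if status is Status.UNKNOWN:
                chosen[sub] = None
                rng.random()  # keep the stream aligned across classes
                continue
            bank = TEMPLATES[(sub, status)]
            rich = [t for t in bank if t.attributes]
            plain = [t for t in bank if not t.attributes]
            use_rich = rng.random() < spec.attribute_rate
            pool = rich if (use_rich and rich) or not plain else plain
            chosen[sub] = rng.choice(pool)

        use_hpi_distractor = rng.random() < spec.distractor_rate
        use_allergy_distractor = rng.random() < spec.distractor_rate
        use_followup_distractor = rng.random() < spec.distractor_rate
        use_body_distractor = rng.random() < spec.distractor_rate
        filler = rng.choice(FILLERS)
        hpi_distractor = rng.choice(DISTRACTORS_HPI)
        allergy_distractor = rng.choice(DISTRACTORS_ALLERGIES)
        body_distractor = rng.choice(DISTRACTORS_BODY)

        parts: list[str] = [f"Record {record_id}.\n"]
        parts.append("HISTORY OF PRESENT ILLNESS: ")
        parts.append(filler)
        if use_hpi_distractor:
            _place(parts, hpi_distractor)
        parts.append("\n")
        parts.append("ALLERGIES: ")
        parts.append(allergy_distractor if use_allergy_distractor else "None known.")
        parts.append("\n")
        # each substance block gets its own line so header-style templates
        # ("Tobacco: None.") sit at a line start, as they would in a real note
        parts.append("SOCIAL HISTORY:\n")
        wrote_social = False
        attr_slots: list[tuple[Substance, Template, int]] = []
        for sub in SUBSTANCES:
            t = chosen[sub]
            if t is None:
                continue
            offset = sum(len(p) for p in parts)
            parts.append(t.text + "\n")
            attr_slots.append((sub, t, offset))
            wrote_social = True
        if use_body_distractor:
            parts.append(body_distractor + "\n")
            wrote_social = True
        if not wrote_social:
            parts.append("Nothing of note.\n")
        parts.append("FOLLOW UP AND INSTRUCTIONS: ")
        parts.append(
            DISTRACTORS_FOLLOWUP[0]
            if use_followup_distractor
            else "Return to clinic in two weeks."
        )
        parts.append("\n")

        text = "".join(parts)
        records.append(Record(record_id=record_id, text=text))

        results = {}
        for sub in SUBSTANCES:
            attrs = []
            t = chosen[sub]
            if t is not None and statuses[sub] in (Status.PAST, Status.CURRENT):
                offset = next(o for s2, t2, o in attr_slots if s2 is sub)
                for kind, substring in t.attributes:
                    assert t.text.count(substring) == 1, (t.text, substring)
                    rel = t.text.find(substring)
                    start, end = offset + rel, offset + rel + len(substring)
                    assert text[start:end] == substring
                    attrs.append(
                        AttributeSpan(kind=kind, text=substring, char_start=start,
                                      char_end=end, substance=sub)
                    )
                    gold_spans.append((record_id, sub, kind, start, end, substring))
            results[sub] = SubstanceResult(
                substance=sub,
                status=statuses[sub],
                attributes=sorted(attrs, key=lambda a: (a.char_start, a.char_end)),
                evidence_sentences=[],
            )
        gold_results.append(
            RecordResult(record_id=record_id, results=results,
                         granularity=Granularity.DOCUMENT)
        )

    return records, gold_results, gold_spans
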