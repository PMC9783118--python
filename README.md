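# substex

Rule-based extraction of **substance-use status and attributes** from
free-text clinical discharge notes.

Clinicians and clinical researchers need a patient's smoking, alcohol and
drug history, but in electronic health records it is usually buried in
narrative text ("Quit tobacco 10 years ago; drinks 1–2 beers per week;
denies illicit drugs"). `substex` reads plain-text discharge summaries and
reports, per record or per sentence, one of four statuses per substance —
**Unknown** (not mentioned), **None** (never used), **Past** (stopped
about a year or more ago), **Current** (use within the past year) — plus
five attribute spans with exact character offsets: **amount**, **type**,
**frequency**, **quit-time** and **period**.

The core is a four-stage rule pipeline:

1. **Relevance** — keyword search with suppression of misleading concepts
   ("smoke inhalation", "drug rash"), restricted sections (ALLERGIES,
   follow-up instructions), non-alcoholic "drink" phrases, and the
   PPD-skin-test reading of "ppd"; records mentioning no substance are
   discarded as Unknown.
2. **Negation** — an extended NegEx: trigger words within a 9-word left /
   2-word right window mark a keyword negated, with seven extensions
   (semantic words like *non-smoker*, `-`/`+` signs, header patterns like
   "Alcohol: None", a "nor" expansion, social and temporal negation
   overrides, and OR aggregation over multiple keywords). Per class *c*
   the evaluation reports sensitivity Sen = TP/(TP+FN), precision
   Pre = TP/(TP+FP) and F1 = 2·Pre·Sen/(Pre+Sen).
3. **Temporal status** — positive records are Current unless past evidence
   links to the keyword under per-term scope rules (same chunk / one word
   after / two words either side / all words before), with
   current-treatment overrides ("nicotine patch", "to quit") and
   closest-keyword assignment in multi-substance sentences.
4. **Attributes** — layered regex, syntactic (cardinal-based) and lexical
   scans extract the five attribute spans and attach each to the adjacent
   substance keyword.

Because real annotated discharge corpora sit behind data-use agreements,
the package ships a seeded synthetic-record generator with gold labels
(`substex.synth`), so the entire pipeline and its evaluation harness run
and are tested with zero downloads. A separate hard-template set encodes
the rule system's documented failure modes, and tests assert the wrong
answers — the limits stay measurable instead of silently patched.

## Worked example

```
$ substex generate --n 5 --seed 3 --out-dir corpus
wrote 5 records and gold.jsonl to corpus
$ substex extract corpus/records -o pred.jsonl
wrote 5 results to pred.jsonl
$ substex evaluate corpus/gold.jsonl pred.jsonl
group           class    Sen     Pre     F1      TP  FP  FN
status/smoking  CURRENT  1.0000  1.0000  1.0000  1   0   0
status/smoking  NONE     1.0000  1.0000  1.0000  1   0   0
status/smoking  PAST     1.0000  1.0000  1.0000  3   0   0
...
attribute   Sen     Pre     F1
AMOUNT      1.0000  1.0000  1.0000
TYPE        1.0000  1.0000  1.0000
FREQUENCY   1.0000  1.0000  1.0000
QUIT_TIME   1.0000  1.0000  1.0000
PERIOD      1.0000  1.0000  1.0000
```

One generated record looks like a miniature discharge summary —

```
Record synthetic-0000.
HISTORY OF PRESENT ILLNESS: The hospital course was uneventful. PPD placed on left forearm.
ALLERGIES: No known drug allergies.
SOCIAL HISTORY:
He smokes about five packs a week.
Remote drug abuse.
FOLLOW UP AND INSTRUCTIONS: Return to clinic in two weeks.
```

— and its JSON-lines result records smoking as CURRENT with amount
`"five packs"` and frequency `"a week"` (exact offsets into the raw text),
drugs as PAST (the "remote … same chunk" rule), and alcohol as UNKNOWN;
the "PPD placed" and "drug allergies" traps are suppressed and contribute
nothing. The perfect scores above say the rules recover exactly what the
generator's templates encode — internal consistency, not real-world
accuracy; see `docs/methods.md` for what that does and does not show.

The same pipeline runs per sentence (`--granularity sentence`) and can
emit BRAT standoff annotations (`--format brat`) for inspection in the
BRAT annotation tool. The library surface mirrors the CLI:

```python
from substex import load_lexicons, run_record, Record

lex = load_lexicons()
result = run_record(Record("note1", "Quit smoking in 1994. Drinks 1-2 beers per week."), lex)
result.results  # per-substance status + attribute spans
```

## Layout

| path | contents |
|---|---|
| `src/substex/model.py` | core types: Record, Mention, Status, AttributeSpan, results |
| `src/substex/io.py` | corpus reader, JSON-lines writer/reader, BRAT standoff writer |
| `src/substex/lexicons.py` + `resources/` | every term inventory, plain-text, overridable |
| `src/substex/preprocess.py` | sentences, tokens, sections, shallow chunks |
| `src/substex/relevance.py` | stage 1: mentions, suppression, Known/Unknown gate |
| `src/substex/negation.py` | stage 2: extended NegEx |
| `src/substex/temporal.py` | stage 3: past/current classification |
| `src/substex/attributes.py` | stage 4: attribute span extraction |
| `src/substex/evaluation.py` | Sen/Pre/F1 per class, span scoring |
| `src/substex/synth.py` | seeded synthetic corpus generator with gold labels |
| `src/substex/pipeline.py`, `cli.py` | orchestration and the `substex` command |
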