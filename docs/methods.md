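# Methods

`substex` implements a four-stage, rule-based system that reads free-text
clinical discharge notes and reports, per record (or per sentence), the
patient's substance-use status for smoking, alcohol and drugs —
`UNKNOWN` (not mentioned), `NONE` (never used), `PAST` (stopped, roughly a
year or more ago), `CURRENT` (use within the recent past) — together with
five attribute spans: amount, type, frequency, quit-time and period. This
note documents the model, its assumptions, the parameters that matter, and
the limits of what the shipped tests demonstrate.

## The pipeline

**Preprocessing.** Sentences split on `.`/`!`/`?` and newlines
(abbreviations and decimals protected); tokens keep clinically meaningful
units whole: hyphenated compounds (`ex-smoker`), sign-prefixed assertions
(`-tob`, `+etho`), numeric ranges (`1-2`, `3–4`), fractions and dates.
Part-of-speech tagging is deliberately minimal and rule-based: the only
distinction the downstream patterns need is cardinal values (`CD`: digits,
ranges, dates, spelled-out numerals plus "half") versus everything else. A
greedy shallow chunker groups maximal determiner/CD/noun-ish runs into
noun phrases, with "to"/"and" admitted between two cardinals so that
"2 and 1/2 to 3 packs" is one chunk; a small closed list of function words
(verbs, prepositions, adverbs) terminates runs. Section headers are
detected at line starts (all-caps always; mixed-case only from a shipped
inventory) and scope both the suppression rules and the header-negation
rule. Window distances everywhere count *word* tokens only, so comma style
cannot change a scope decision.

**Stage 1 — relevance.** Keyword token-sequence matches (longest match
first, case-insensitive) produce mentions, which four ordered suppression
passes can deactivate: (a) the mention lies inside a misleading concept
("smoke inhalation", "vaginal pack", "drug rash"); (b) alcohol/drug
mentions in restricted sections (`ALLERGIES`, `FOLLOW_UP_INSTRUCTIONS`;
smoking is unrestricted); (c) "drink" with a non-alcoholic drink (water,
juice, coffee) in the same or adjacent chunk; (d) "ppd" not immediately
preceded by a number (the PPD skin test reading). A sentence containing
"quit" but no keyword is linked to the nearest preceding mention-bearing
sentence and inherits its substances. A record with no active mention of
any substance is `UNKNOWN` for all three and skips the later stages.

**Stage 2 — extended NegEx.** Base algorithm: a *pre-trigger* (no, not,
denies, never, without, ...) within 9 word tokens before the keyword, or a
*post-trigger* (denied, was/were denied, no, ...) within 2 word tokens
after it, marks the mention negated; conjunctions (`nor`, `but`) terminate
a trigger's scope. Active-voice verbs like "denies" are pre-triggers only —
they never negate backwards, which is exactly why "former smoker, he denies
any use of tobacco" keeps "smoker" positive. Seven extensions are layered
on, applied in a fixed order with exactly one rule recorded per decision:
semantic negation words (`non-smoker`); polarity signs (`-tob` negative,
`+etho` forced positive; an alphabetic hyphen compound is not a sign);
header negation ("Alcohol: None"); the plain windows; a `nor` expansion
(the first keyword after "nor" is negated regardless of distance); social
overrides ("socially, rare, occasional" attached to the *closest preceding*
keyword cancel its negation); temporal overrides ("since, for, last, quit"
between trigger and keyword or shortly after it) cancel the negation *and*
mark the mention as past evidence — "has not drunk alcohol since 1984" is a
past drinker, not a non-drinker. Aggregation is a logical OR: any positive
mention makes the sentence, and the document, positive. With
`NegationConfig(extensions=False)` the system degrades to plain windows
with negative-dominant aggregation, which reproduces the failures the
extensions exist to fix; this baseline is kept as a first-class
configuration because it demonstrates that the extensions, not the windows,
carry the accuracy.

**Stage 3 — temporal status.** Positive mentions default to `CURRENT`
unless past evidence links to them under a per-term scope rule:
same-chunk (remote, in the past, in the last, previous), one word after
(former, prior, recovered, distant), two words either side (past), all
words before (until, inactive, none since), or one-word-after falling back
to all-words-before (discontinued, quit, ago, stopped). "ex-" prefixed
keywords are intrinsic past markers. Treatment and intent terms ("nicotine
patch", "smoking cessation", "ethanol abstinence", "to stop", "to quit")
mark the sentence current and override past evidence within it. When
several substances share a sentence, a past term attaches only to the
closest mention (ties break toward the mention before the term). The
document status per substance is `CURRENT` if *any* mention is current,
else `PAST` — the per-drug OR (past user of one drug, current user of
another ⇒ current) applied uniformly to all three substances, since any
current-evidence sentence establishes use within the past year.

**Stage 4 — attributes.** Run only on sentences holding positive mentions
of substances whose final status is `PAST`/`CURRENT` (so `UNKNOWN`/`NONE`
substances never carry attributes). Amounts go through three scans with
strict precedence: numeric regex (`1 to 2 packs`, `3–4 drinks`, `100 pk`),
spelled-cardinal syntactic patterns within the chunk (`five packs`,
`two to three beers`, `up to one pint`), then lexical descriptors
(`heavy`, `minimal`, `significant`) adjacent to the keyword's chunk.
Types come from three per-substance sub-lexicons. Frequencies follow
`(amount | times) (per|a|/|every|-) (day|week|month|year)` with a lexical
fallback (`occ`, `nightly`, `daily`, ...); the span covers the connector
and period word, plus the "times" head and its own cardinal when present
("one to two times a month"). Quit-times anchor on a quit verb
(quit/stop/stopped/discontinued/until/since/"last use|drink") followed
within three word tokens by a cardinal, or on a bare "CD years ago";
periods anchor on for/times/×/x plus a cardinal (ranges allowed) plus a
period word, and include the connector ("for 8 to 9 years", "×35 years").
When both patterns could claim one cardinal, the quit reading wins when a
quit verb or "ago" backs it; a period connector between the quit verb and
the cardinal hands the span to the period pattern ("stopped smoking for 30
years" is a period, not a quit date). Spans attach to the adjacent
(minimum word-distance) mention, ties toward the nearest prior mention;
orphan quit sentences inherit their linked substance. No unit
normalisation is performed — the system evaluates extraction, not
canonicalisation, so raw spans are emitted.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_left_scope` | 9 words | pre-trigger window before a keyword |
| `max_right_scope` | 2 words | post-trigger window after a keyword |
| `extensions` | on | the seven negation extensions + OR aggregation |
| restricted sections | ALLERGIES, FOLLOW_UP_INSTRUCTIONS (alcohol, drugs) | Stage-1 suppression scope |
| `GenerationSpec.n_records` | 100 | synthetic corpus size |
| `GenerationSpec.class_mix` | uniform over 4 classes | per-substance status mix |
| `GenerationSpec.distractor_rate` | 0.3 | probability of each distractor slot |
| `GenerationSpec.attribute_rate` | 0.6 | probability of an attribute-bearing template |

The window defaults (9, 2) are the operating point of the rule system; both
are CLI flags (`--left-scope/--right-scope`) and sweeping them is part of
the test suite. All lexicons live in plain-text resource files (one term
per line, TSV where a term carries a scope or substance column) and can be
overridden per list through a YAML config.

## The synthetic generator, and what passing tests show

No public, unrestricted corpus of annotated discharge summaries exists for
this task, so the package ships a seeded generator that emulates the
*structure* the rules consume: section scaffolding (history of present
illness, allergies, social history, follow-up instructions), per-substance
sentences drawn from a template bank keyed by the intended gold label, and
distractors that exercise every suppression rule (misleading concepts,
restricted-section traps, non-alcoholic "drink" phrases, unqualified
"PPD"). Gold statuses and attribute spans are fixed at template-authoring
time; the same spec and seed always produce a byte-identical corpus. A
separate hard-template set encodes the system's *documented failure modes*
("Smoking, no alcohol" negating both; "Abuse of drugs or alcohol were
denied" missing the far trigger; the misspelling "barbituate") with the
true clinical label alongside the wrong output the rules are expected to
produce — fidelity tests assert the wrong answer, keeping the system's
limits measurable instead of silently patched.

The closed-loop test (generate → extract → score, 500 records, uniform
mix, distractor rate 0.3) must reach sensitivity = precision = F1 = 1.0
for every substance, status class and attribute kind. This demonstrates
internal consistency — the rules recover exactly what the templates
encode, through all four stages and both serialisation paths — not
real-world accuracy. Real notes contain misspellings, family-member
attributions ("father smoked"), ungrammatical fragments and section
conventions the generator does not model; performance on such text is
bounded by the failure modes above, and family-member subject analysis and
spelling correction are deliberately out of scope.

## Numerical and design choices

* Offsets are 0-based, half-open character offsets into the raw text
  everywhere (BRAT-compatible); every emitted span must slice back to its
  surface string exactly, and the BRAT writer refuses to write otherwise.
* Suppression order (misleading → section → non-alcoholic → ppd) is fixed;
  it affects only which reason is recorded, never whether a mention is
  active.
* Evaluation reports per-class sensitivity, precision and F1; a class
  absent from both gold and prediction reports null rather than zero, and
  macro averages run over classes present in gold. Attribute matching is
  exact span equality by default with a lenient overlap mode.
* Status scoring and span scoring are implemented directly from confusion
  counts; the test suite cross-checks the label metrics against
  scikit-learn on random label sequences.
* Sentence-level mode derives sentence statuses from the same per-mention
  decisions as document mode, so the document status is always recoverable
  from the per-sentence statuses by rank aggregation
  (CURRENT > PAST > NONE > UNKNOWN); a property test sweeps generated
  corpora to hold this invariant.
* Problem sizes in tests and in `scripts/acceptance.py` (500-record
  corpora) were chosen to make the law-of-large-numbers checks on the
  class mix meaningful while keeping the whole suite near-instant.

## Known limitations

* Lexicons are seeded from the terms the underlying rule system names plus
  clearly marked extension sections (inflections, "drug/drugs", "pack");
  they are far smaller than a production vocabulary.
* No misspelling tolerance, no family-member subject analysis, no
  uncertainty/hedging classes, no date arithmetic against the admission
  date (the one-year boundary between past and current is resolved
  lexically, not temporally).
* "weed" stays in the smoking lexicon as inherited, although it is
  ontologically a drug term.
* One annotated-example idiosyncrasy is not reproduced: "cocaine abuse"
  labelled as a drug *amount*; the system extracts "cocaine" as a drug
  type instead.
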