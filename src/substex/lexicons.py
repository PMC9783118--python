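"""Term inventories consumed by the four extraction stages.

All matching in the pipeline is case-insensitive; terms are stored
lower-cased and deduplicated. Multi-word terms are matched as contiguous
token sequences, never as raw substrings. Resource files ship with the
package (one term per line, ``#`` comments; TSV where a term carries a
scope or substance column) and any list can be overridden via a YAML
config mapping list names to file paths.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import yaml

from .model import ConfigurationError, Substance


class PastScope(enum.Enum):
    SAME_CHUNK = "SAME_CHUNK"
    ONE_AFTER = "ONE_AFTER"
    TWO_BEFORE_TWO_AFTER = "TWO_BEFORE_TWO_AFTER"
    ALL_BEFORE = "ALL_BEFORE"
    ONE_AFTER_ELSE_ALL_BEFORE = "ONE_AFTER_ELSE_ALL_BEFORE"


@dataclass(frozen=True)
class PastTermRule:
    """A past-status term with the search scope used to link it to a keyword."""

    term: str
    scope: PastScope

    @property
    def method(self) -> str:
        # chunking is used exactly for same-chunk terms, windows otherwise
        return "CHUNKING" if self.scope is PastScope.SAME_CHUNK else "WINDOW"


@dataclass
class LexiconSet:
    smoking_keywords: frozenset[str]
    alcohol_keywords: frozenset[str]
    drug_keywords: frozenset[str]
    misleading_concepts: frozenset[str]
    non_alcoholic_drinks: frozenset[str]
    negation_triggers: frozenset[str]
    negation_post_triggers: frozenset[str]
    semantic_negation_words: frozenset[str]
    overrides_social: frozenset[str]
    overrides_temporal: frozenset[str]
    past_term_rules: tuple[PastTermRule, ...]
    current_indicator_terms: dict[str, str]  # term -> "smoking"|"alcohol"|"drugs"|"ANY"
    type_terms: dict[Substance, frozenset[str]]
    amount_lexical_terms: frozenset[str]
    frequency_lexical_terms: frozenset[str]
    unit_nouns: frozenset[str]
    frequency_period_words: frozenset[str] = field(
        default_factory=lambda: frozenset(
            {"day", "days", "week", "weeks", "month", "months", "year", "years", "yr", "yrs"}
        )
    )
    restricted_sections: dict[Substance, frozenset[str]] = field(
        default_factory=lambda: {
            Substance.SMOKING: frozenset(),
            Substance.ALCOHOL: frozenset({"ALLERGIES", "FOLLOW_UP_INSTRUCTIONS"}),
            Substance.DRUG: frozenset({"ALLERGIES", "FOLLOW_UP_INSTRUCTIONS"}),
        }
    )
    section_headers: dict[str, str] = field(default_factory=dict)  # header -> canonical
    #: sign characters whose attachment to a keyword asserts polarity
    negation_signs: dict[str, str] = field(
        default_factory=lambda: {"-": "NEGATIVE", "+": "POSITIVE"}
    )

    def keywords_for(self, substance: Substance) -> frozenset[str]:
        return {
            Substance.SMOKING: self.smoking_keywords,
            Substance.ALCOHOL: self.alcohol_keywords,
            Substance.DRUG: self.drug_keywords,
        }[substance]

    @property
    def all_keywords(self) -> frozenset[str]:
        return self.smoking_keywords | self.alcohol_keywords | self.drug_keywords


_LIST_FILES = {
    "smoking_keywords": "smoking_keywords.txt",
    "alcohol_keywords": "alcohol_keywords.txt",
    "drug_keywords": "drug_keywords.txt",
    "misleading_concepts": "misleading_concepts.txt",
    "non_alcoholic_drinks": "non_alcoholic.txt",
    "negation_triggers": "negation_triggers.txt",
    "negation_post_triggers": "negation_post_triggers.txt",
    "semantic_negation_words": "semantic_negation.txt",
    "overrides_social": "overrides_social.txt",
    "overrides_temporal": "overrides_temporal.txt",
    "amount_lexical_terms": "amount_lexical.txt",
    "frequency_lexical_terms": "frequency_lexical.txt",
    "unit_nouns": "unit_nouns.txt",
}

_MANDATORY = set(_LIST_FILES)


def _resource_path(name: str) -> Path:
    return Path(str(importlib_resources.files("substex") / "resources" / name))


def _read_lines(path: Path) -> list[str]:
    out = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def _term_set(path: Path, list_name: str) -> frozenset[str]:
    terms = [t.lower() for t in _read_lines(path)]
    if len(terms) != len(set(terms)):
        dupes = sorted({t for t in terms if terms.count(t) > 1})
        warnings.warn(f"duplicate terms in {list_name}: {dupes}; deduplicating")
    return frozenset(terms)


def load_lexicons(config_path: str | Path | None = None) -> LexiconSet:
    """Load the shipped default lexicons, optionally overridden by a YAML config.

    The config maps list names (as in :class:`LexiconSet`) to file paths.
    """
    overrides: dict[str, str] = {}
    if config_path is not None:
        with open(config_path, encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}

    def path_for(name: str, default_file: str) -> Path:
        if name in overrides:
            return Path(overrides[name])
        return _resource_path(default_file)

    lists = {
        name: _term_set(path_for(name, fname), name) for name, fname in _LIST_FILES.items()
    }
    for name in _MANDATORY:
        if not lists[name]:
            raise ConfigurationError(f"mandatory lexicon {name!r} is empty")

    past_rules = []
    for line in _read_lines(path_for("past_term_rules", "past_terms.tsv")):
        term, _, scope = line.partition("\t")
        if not scope:
            raise ConfigurationError(f"past-terms file line missing scope column: {line!r}")
        past_rules.append(PastTermRule(term.strip().lower(), PastScope(scope.strip())))

    indicators = {}
    for line in _read_lines(path_for("current_indicator_terms", "current_indicators.tsv")):
        term, _, sub = line.partition("\t")
        indicators[term.strip().lower()] = (sub.strip() or "ANY")

    type_terms: dict[Substance, set[str]] = {s: set() for s in Substance}
    sub_by_key = {s.json_key: s for s in Substance}
    for line in _read_lines(path_for("type_terms", "type_terms.tsv")):
        term, _, sub = line.partition("\t")
        type_terms[sub_by_key[sub.strip()]].add(term.strip().lower())

    headers = {}
    for line in _read_lines(path_for("section_headers", "section_headers.tsv")):
        header, _, canonical = line.partition("\t")
        headers[header.strip().lower()] = canonical.strip()

    return LexiconSet(
        smoking_keywords=lists["smoking_keywords"],
        alcohol_keywords=lists["alcohol_keywords"],
        drug_keywords=lists["drug_keywords"],
        misleading_concepts=lists["misleading_concepts"],
        non_alcoholic_drinks=lists["non_alcoholic_drinks"],
        negation_triggers=lists["negation_triggers"],
        negation_post_triggers=lists["negation_post_triggers"],
        semantic_negation_words=lists["semantic_negation_words"],
        overrides_social=lists["overrides_social"],
        overrides_temporal=lists["overrides_temporal"],
        past_term_rules=tuple(past_rules),
        current_indicator_terms=indicators,
        type_terms={s: frozenset(v) for s, v in type_terms.items()},
        amount_lexical_terms=lists["amount_lexical_terms"],
        frequency_lexical_terms=lists["frequency_lexical_terms"],
        unit_nouns=lists["unit_nouns"],
        section_headers=headers,
    )


def validate_lexicons(lex: LexiconSet) -> list[str]:
    """Check LexiconSet invariants; returns human-readable diagnostics."""
    diags: list[str] = []
    keyword_tokens = set()
    for kw in lex.all_keywords:
        keyword_tokens.update(kw.split())
    for concept in lex.misleading_concepts:
        if not any(tok in keyword_tokens for tok in concept.split()):
            diags.append(
                f"misleading concept {concept!r} contains no substance keyword token"
            )
    for name in ("smoking_keywords", "alcohol_keywords", "drug_keywords"):
        terms = getattr(lex, name)
        for t in terms:
            if t != t.lower():
                diags.append(f"{name}: term {t!r} is not lower-cased")
    scopes = {r.scope for r in lex.past_term_rules}
    for scope in PastScope:
        if scope not in scopes:
            diags.append(f"past_term_rules: no rule uses scope {scope.value}")
    for term, sub in lex.current_indicator_terms.items():
        if sub not in {"smoking", "alcohol", "drugs", "ANY"}:
            diags.append(f"current indicator {term!r} has unknown substance {sub!r}")
    return diags
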