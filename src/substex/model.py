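"""Core data types for clinical substance-use extraction.

Every span is expressed in 0-based, half-open character offsets into the raw
record text (BRAT-compatible). The raw text is never modified; slicing the
record text with a span must reproduce the span's surface string exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Substance(enum.Enum):
    """The three substance-use classes tracked per record."""

    SMOKING = "smoking"
    ALCOHOL = "alcohol"
    DRUG = "drugs"

    @property
    def json_key(self) -> str:
        return self.value


SUBSTANCES = (Substance.SMOKING, Substance.ALCOHOL, Substance.DRUG)


class Status(enum.Enum):
    """Substance-use status of a record (or sentence).

    UNKNOWN: the text says nothing about use of the substance.
    NONE: the text asserts the patient never used it.
    PAST: use stopped (roughly: a year or more ago).
    CURRENT: use within the recent past, the default for positive evidence.
    """

    UNKNOWN = "UNKNOWN"
    NONE = "NONE"
    PAST = "PAST"
    CURRENT = "CURRENT"


class AttributeKind(enum.Enum):
    AMOUNT = "AMOUNT"
    TYPE = "TYPE"
    FREQUENCY = "FREQUENCY"
    QUIT_TIME = "QUIT_TIME"
    PERIOD = "PERIOD"


class SourceScan(enum.Enum):
    """Which scanning level produced an amount/frequency span."""

    REGEX = "REGEX"
    SYNTACTIC = "SYNTACTIC"
    LEXICAL = "LEXICAL"


class SuppressionReason(enum.Enum):
    NONE = "NONE"
    MISLEADING = "MISLEADING"
    SECTION = "SECTION"
    NON_ALCOHOLIC = "NON_ALCOHOLIC"
    PPD_UNQUALIFIED = "PPD_UNQUALIFIED"


class Granularity(enum.Enum):
    DOCUMENT = "DOCUMENT"
    SENTENCE = "SENTENCE"


@dataclass(frozen=True)
class Record:
    """One clinical note: an identifier plus its raw text."""

    record_id: str
    text: str


@dataclass
class Token:
    text: str
    char_start: int
    char_end: int
    index: int  # position within the owning sentence
    is_word: bool
    pos_tag: str  # "CD" for cardinals/ranges/dates/spelled numbers, else coarse

    @property
    def norm(self) -> str:
        return self.text.lower()


@dataclass
class Sentence:
    index: int
    char_start: int
    char_end: int
    tokens: list[Token]
    section: str = "BODY"

    def text_of(self, record_text: str) -> str:
        return record_text[self.char_start:self.char_end]

    @property
    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_word]


@dataclass
class Section:
    header_text: str
    canonical_name: str
    char_start: int
    char_end: int
    header_char_start: int = 0
    header_char_end: int = 0


@dataclass
class Chunk:
    label: str  # "NP" or "O"
    token_span: tuple[int, int]  # half-open token index range within a sentence


@dataclass
class Mention:
    substance: Substance
    keyword: str
    sentence_index: int
    token_span: tuple[int, int]
    char_start: int
    char_end: int
    suppressed: bool = False
    suppression_reason: SuppressionReason = SuppressionReason.NONE
    is_ex_prefixed: bool = False  # token like "ex-smoker"

    @property
    def active(self) -> bool:
        return not self.suppressed


@dataclass(frozen=True)
class AttributeSpan:
    kind: AttributeKind
    text: str
    char_start: int
    char_end: int
    substance: Optional[Substance] = None
    source_scan: Optional[SourceScan] = None

    def validate_against(self, record_text: str) -> None:
        if record_text[self.char_start:self.char_end] != self.text:
            raise IntegrityError(
                f"span text {self.text!r} does not match record slice "
                f"[{self.char_start}:{self.char_end}]"
            )


@dataclass
class SubstanceResult:
    substance: Substance
    status: Status
    attributes: list[AttributeSpan] = field(default_factory=list)
    evidence_sentences: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status in (Status.UNKNOWN, Status.NONE) and self.attributes:
            raise ValueError("attributes must be empty for UNKNOWN/NONE status")


@dataclass
class RecordResult:
    record_id: str
    results: dict[Substance, SubstanceResult]
    granularity: Granularity = Granularity.DOCUMENT
    per_sentence: Optional[dict[int, dict[Substance, Status]]] = None
    discarded: bool = False

    def status(self, substance: Substance) -> Status:
        return self.results[substance].status


class SubstexError(Exception):
    """Base class for package errors."""


class EmptyCorpusError(SubstexError):
    pass


class ConfigurationError(SubstexError):
    pass


class IntegrityError(SubstexError):
    pass
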