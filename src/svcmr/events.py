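"""Structural-variant event model and classification.

Candidate events come from two detection channels: split/discordant reads
(indels and long deletions/tandem duplications) and read depth (copy-number
variable sites, >= 2 kb).  Each event is assigned to exactly one of six
mutation categories based on its channel, type and length.  The channel is
authoritative: long-deletion and CNV-deletion length ranges overlap, so
length alone cannot decide the category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence


class SVType(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    TANDEM_DUPLICATION = "tandem_duplication"
    CNV_DELETION = "cnv_deletion"
    CNV_DUPLICATION = "cnv_duplication"


class Channel(str, Enum):
    SPLIT_READ = "split_read"
    READ_DEPTH = "read_depth"


class Category(str, Enum):
    SHORT_INSERTION = "short_insertion"
    SHORT_DELETION = "short_deletion"
    LONG_DELETION = "long_deletion"
    LONG_TANDEM_DUPLICATION = "long_tandem_duplication"
    CNV_DELETION = "cnv_deletion"
    CNV_DUPLICATION = "cnv_duplication"


#: sign of the length change: +1 for insertions/duplications, -1 for deletions
SIGN = {
    SVType.INSERTION: +1,
    SVType.TANDEM_DUPLICATION: +1,
    SVType.CNV_DUPLICATION: +1,
    SVType.DELETION: -1,
    SVType.CNV_DELETION: -1,
}

#: coarse family used when matching call sets against truth sets, where the
#: detection channel cannot be recovered from sequence alone
CATEGORY_FAMILY = {
    Category.SHORT_INSERTION: "insertion",
    Category.SHORT_DELETION: "deletion",
    Category.LONG_DELETION: "deletion",
    Category.CNV_DELETION: "deletion",
    Category.LONG_TANDEM_DUPLICATION: "duplication",
    Category.CNV_DUPLICATION: "duplication",
}


class ValidationError(ValueError):
    """An event violates a structural invariant."""


@dataclass
class CategorySpec:
    """Length thresholds separating the six mutation categories.

    Defaults: events < 50 bp are "short" indels, >= 50 bp are "long"
    deletions/duplications, and read-depth (CNV) events must be >= 2,000 bp.
    """

    short_max: int = 49
    long_min: int = 50
    cnv_min: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.short_max < self.long_min <= self.cnv_min):
            raise ValueError(
                f"require 0 < short_max < long_min <= cnv_min, got "
                f"{self.short_max}, {self.long_min}, {self.cnv_min}"
            )


@dataclass
class EventTableRow:
    """One candidate structural variant on one MA line.

    Coordinates are 0-based half-open.  For insertions ``end == start`` and
    ``length`` is the number of inserted bases; for all other types
    ``end - start == length``.
    """

    line_id: str
    contig: str
    start: int
    end: int
    sv_type: SVType
    length: int
    channel: Channel
    copy_number_change: Optional[float] = None

    def __post_init__(self) -> None:
        self.sv_type = SVType(self.sv_type)
        self.channel = Channel(self.channel)
        self.validate()

    def validate(self) -> None:
        if self.length < 1:
            raise ValidationError(f"length must be >= 1, got {self.length}")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.sv_type is SVType.INSERTION:
            if self.end != self.start:
                raise ValidationError(
                    f"insertion must have end == start, got [{self.start}, {self.end})"
                )
        elif self.end - self.start != self.length:
            raise ValidationError(
                f"end - start must equal length for {self.sv_type.value}: "
                f"[{self.start}, {self.end}) vs length {self.length}"
            )


@dataclass
class SVEvent(EventTableRow):
    """A classified structural variant."""

    category: Category = field(default=None)  # type: ignore[assignment]
    signed_length_change: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.category is not None:
            self.category = Category(self.category)


def classify(event: EventTableRow, spec: CategorySpec | None = None) -> SVEvent:
    """Assign an event to one of the six mutation categories.

    The detection channel decides first: read-depth events are CNV sites
    and must be at least ``spec.cnv_min`` long; split-read events are short
    (< ``spec.long_min``) or long (>= ``spec.long_min``) indels/duplications.

    Raises
    ------
    ValidationError
        If channel, type and length are inconsistent (e.g. a read-depth
        event below the CNV minimum, or a split-read event typed as CNV).
    """
    spec = spec or CategorySpec()
    if event.channel is Channel.READ_DEPTH:
        if event.sv_type not in (SVType.CNV_DELETION, SVType.CNV_DUPLICATION):
            raise ValidationError(
                f"read_depth events must be cnv_* typed, got {event.sv_type.value}"
            )
        if event.length < spec.cnv_min:
            raise ValidationError(
                f"read_depth event of {event.length} bp below CNV minimum "
                f"{spec.cnv_min} bp"
            )
        category = (
            Category.CNV_DELETION
            if event.sv_type is SVType.CNV_DELETION
            else Category.CNV_DUPLICATION
        )
    else:
        if event.sv_type in (SVType.CNV_DELETION, SVType.CNV_DUPLICATION):
            raise ValidationError("split_read events cannot carry a cnv_* sv_type")
        short = event.length < spec.long_min
        if event.sv_type is SVType.INSERTION:
            if not short:
                raise ValidationError(
                    f"insertions are short by definition (< {spec.long_min} bp), "
                    f"got {event.length} bp"
                )
            category = Category.SHORT_INSERTION
        elif event.sv_type is SVType.DELETION:
            category = Category.SHORT_DELETION if short else Category.LONG_DELETION
        else:  # tandem duplication
            if short:
                raise ValidationError(
                    f"tandem duplications are long by definition "
                    f"(>= {spec.long_min} bp), got {event.length} bp"
                )
            category = Category.LONG_TANDEM_DUPLICATION
    return SVEvent(
        line_id=event.line_id,
        contig=event.contig,
        start=event.start,
        end=event.end,
        sv_type=event.sv_type,
        length=event.length,
        channel=event.channel,
        copy_number_change=event.copy_number_change,
        category=category,
        signed_length_change=SIGN[event.sv_type] * event.length,
    )


def count_by_category(
    events: Sequence[SVEvent], line: str | None = None
) -> dict[Category, int]:
    """Count events per category, optionally restricted to one MA line.

    Every category is present in the result; categories without events
    report 0.
    """
    counts = Counter(
        e.category for e in events if line is None or e.line_id == line
    )
    return {cat: counts.get(cat, 0) for cat in Category}


__all__ = [
    "SVType",
    "Channel",
    "Category",
    "SIGN",
    "CATEGORY_FAMILY",
    "ValidationError",
    "CategorySpec",
    "EventTableRow",
    "SVEvent",
    "classify",
    "count_by_category",
    "replace",
]
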