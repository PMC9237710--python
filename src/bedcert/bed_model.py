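"""Domain types for BED records, variants and dialects.

The BED format stores genomic intervals as plain-text lines of 3 to 12
whitespace-delimited fields.  The first three fields (``chrom``,
``chromStart``, ``chromEnd``) are mandatory; the remaining nine are
optional but ordered — every field before the last one used must be
present.  Coordinates are 0-based, half-open: ``chromStart`` is
inclusive, ``chromEnd`` exclusive, so the interval length is
``chromEnd - chromStart`` (zero-length intervals are legal).

This module is the single home for field semantics.  Validation of raw
text against the rules lives in :mod:`bedcert.strict_validator`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple, Union

__all__ = [
    "STANDARD_FIELD_NAMES",
    "STANDARD_N",
    "BedError",
    "VariantError",
    "SerializationError",
    "BedVariant",
    "Dialect",
    "TABS",
    "FLEXIBLE",
    "BedRecord",
    "detect_variant",
    "standard_variants",
    "serialize_record",
]

#: Ordered names of the 12 standard fields.
STANDARD_FIELD_NAMES: Tuple[str, ...] = (
    "chrom",
    "chromStart",
    "chromEnd",
    "name",
    "score",
    "strand",
    "thickStart",
    "thickEnd",
    "itemRgb",
    "blockCount",
    "blockSizes",
    "blockStarts",
)

#: Field counts of the 8 standard variants (BED10 and BED11 are prohibited).
STANDARD_N = frozenset({3, 4, 5, 6, 7, 8, 9, 12})

_UNSIGNED_RE = re.compile(r"[0-9]+\Z")


class BedError(Exception):
    """Base error; carries a symbolic ``code``."""

    code = "BED_ERROR"

    def __init__(self, message: str, code: Optional[str] = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class VariantError(BedError):
    """Raised when a field count does not map to a legal variant."""


class SerializationError(BedError):
    """Raised when a record cannot be written under the requested dialect."""


@dataclass(frozen=True, order=True)
class BedVariant:
    """The (n, m) designation of a BED file.

    ``BEDn`` is a file with exactly the first *n* standard fields;
    ``BEDn+m`` has *n* standard fields followed by *m* custom fields.
    """

    n: int
    m: int = 0

    def __post_init__(self) -> None:
        if not (3 <= self.n <= 12):
            raise ValueError(f"n must be 3-12, got {self.n}")
        if self.m < 0:
            raise ValueError(f"m must be non-negative, got {self.m}")

    @property
    def standard(self) -> bool:
        """True for the 8 standard variants: BED3-BED9 and BED12."""
        return self.m == 0 and self.n in STANDARD_N

    @property
    def field_count(self) -> int:
        return self.n + self.m

    def __str__(self) -> str:
        return f"BED{self.n}" if self.m == 0 else f"BED{self.n}+{self.m}"


def standard_variants() -> Tuple[BedVariant, ...]:
    """The 8 standard variants, in ascending field-count order."""
    return tuple(BedVariant(n) for n in sorted(STANDARD_N))


@dataclass(frozen=True)
class Dialect:
    """Concrete whitespace and line-handling rules for one file.

    ``tabs`` mode splits on single tab characters, preserving empty
    fields; ``flexible`` mode splits on maximal runs of tabs and spaces,
    which implies no field value may itself contain a space.
    """

    whitespace: Literal["tabs", "flexible"] = "flexible"
    allow_blank_lines: bool = True
    skip_comment_lines: bool = False


TABS = Dialect(whitespace="tabs")
FLEXIBLE = Dialect(whitespace="flexible")


@dataclass(frozen=True)
class BedRecord:
    """One parsed BED data line.

    ``itemRgb`` is either the literal integer 0 or an (r, g, b) triple
    with components in 0-255.  ``blockStarts`` are relative to
    ``chromStart``.  Extra custom fields of a BEDn+m line are kept
    verbatim in ``custom``.
    """

    chrom: str
    chromStart: int
    chromEnd: int
    name: Optional[str] = None
    score: Optional[int] = None
    strand: Optional[str] = None
    thickStart: Optional[int] = None
    thickEnd: Optional[int] = None
    itemRgb: Union[int, Tuple[int, int, int], None] = None
    blockCount: Optional[int] = None
    blockSizes: Optional[Tuple[int, ...]] = None
    blockStarts: Optional[Tuple[int, ...]] = None
    custom: Tuple[str, ...] = field(default=())

    def optional_values(self) -> Tuple[object, ...]:
        return (
            self.name,
            self.score,
            self.strand,
            self.thickStart,
            self.thickEnd,
            self.itemRgb,
            self.blockCount,
            self.blockSizes,
            self.blockStarts,
        )

    def n_fields(self) -> int:
        """Number of standard fields populated (3-12)."""
        n = 3
        for value in self.optional_values():
            if value is None:
                break
            n += 1
        return n

    @classmethod
    def from_fields(cls, fields: list, variant: BedVariant) -> "BedRecord":
        """Parse raw field texts into a typed record.

        Raises ``ValueError`` on any token that does not parse; this is
        a strict constructor, not a validator — rule-by-rule diagnosis
        belongs to :func:`bedcert.strict_validator.validate_line`.
        """
        if len(fields) != variant.field_count:
            raise ValueError(
                f"expected {variant.field_count} fields for {variant}, got {len(fields)}"
            )
        std = fields[: variant.n]
        kwargs: dict = {
            "chrom": std[0],
            "chromStart": _parse_uint(std[1], "chromStart"),
            "chromEnd": _parse_uint(std[2], "chromEnd"),
            "custom": tuple(fields[variant.n :]),
        }
        if variant.n >= 4:
            kwargs["name"] = std[3]
        if variant.n >= 5:
            kwargs["score"] = int(std[4])
        if variant.n >= 6:
            kwargs["strand"] = std[5]
        if variant.n >= 7:
            kwargs["thickStart"] = _parse_uint(std[6], "thickStart")
        if variant.n >= 8:
            kwargs["thickEnd"] = _parse_uint(std[7], "thickEnd")
        if variant.n >= 9:
            kwargs["itemRgb"] = _parse_rgb(std[8])
        if variant.n >= 10:
            kwargs["blockCount"] = _parse_uint(std[9], "blockCount")
        if variant.n >= 11:
            kwargs["blockSizes"] = _parse_int_list(std[10])
        if variant.n >= 12:
            kwargs["blockStarts"] = _parse_int_list(std[11])
        return cls(**kwargs)


def _parse_uint(token: str, what: str) -> int:
    # Decimal digit strings only: no sign, no exponent, no leading '+'.
    if not _UNSIGNED_RE.match(token):
        raise ValueError(f"{what} is not an unsigned decimal integer: {token!r}")
    return int(token)


def _parse_rgb(token: str) -> Union[int, Tuple[int, int, int]]:
    if token == "0":
        return 0
    parts = token.split(",")
    if len(parts) != 3:
        raise ValueError(f"itemRgb must be '0' or an R,G,B triple: {token!r}")
    rgb = tuple(_parse_uint(p, "itemRgb component") for p in parts)
    if any(c > 255 for c in rgb):
        raise ValueError(f"itemRgb component out of 0-255: {token!r}")
    return rgb  # type: ignore[return-value]


def _parse_int_list(token: str) -> Tuple[int, ...]:
    # One trailing comma is tolerated (widely emitted by UCSC tools).
    body = token[:-1] if token.endswith(",") else token
    if body == "":
        raise ValueError("empty block list")
    return tuple(_parse_uint(p, "block list entry") for p in body.split(","))


def detect_variant(
    field_count: int,
    mode: Literal["strict", "custom"] = "strict",
    declared_n: Optional[int] = None,
) -> BedVariant:
    """Map a per-line field count to a :class:`BedVariant`.

    In strict mode only the 8 standard counts are accepted; 10 and 11
    raise ``PROHIBITED_VARIANT`` and anything outside 3-12 raises
    ``MALFORMED_FIELD_COUNT``.  In custom mode the first ``declared_n``
    fields (default 3, the only guaranteed ones) are standard and the
    rest custom.
    """
    if mode == "strict":
        if field_count in (10, 11):
            raise VariantError(
                f"BED{field_count} is prohibited as a standard variant",
                code="PROHIBITED_VARIANT",
            )
        if field_count < 3 or field_count > 12:
            raise VariantError(
                f"a BED line must have 3-12 fields, got {field_count}",
                code="MALFORMED_FIELD_COUNT",
            )
        return BedVariant(field_count)
    if mode == "custom":
        n = 3 if declared_n is None else declared_n
        if not (3 <= n <= 12):
            raise VariantError(
                f"declared n must be 3-12, got {n}", code="MALFORMED_FIELD_COUNT"
            )
        if field_count < n:
            raise VariantError(
                f"line has {field_count} fields but {n} standard fields declared",
                code="MALFORMED_FIELD_COUNT",
            )
        return BedVariant(n, field_count - n)
    raise ValueError(f"unknown mode: {mode!r}")


def _format_rgb(value: Union[int, Tuple[int, int, int]]) -> str:
    if isinstance(value, int):
        return str(value)
    return ",".join(str(c) for c in value)


def serialize_record(
    record: BedRecord,
    variant: BedVariant,
    delimiter: Literal["tab", "space"] = "tab",
) -> str:
    """Render ``record`` as one ``variant``-shaped line (no newline).

    Space-delimited output is refused with ``DELIMITER_CONFLICT`` if any
    field value itself contains a space, since the result could not be
    re-split correctly.
    """
    opt = record.optional_values()
    fields = [record.chrom, str(record.chromStart), str(record.chromEnd)]
    for i in range(variant.n - 3):
        value = opt[i]
        if value is None:
            raise SerializationError(
                f"record lacks {STANDARD_FIELD_NAMES[3 + i]} required by {variant}",
                code="MISSING_FIELD",
            )
        if i == 5:  # itemRgb
            fields.append(_format_rgb(value))  # type: ignore[arg-type]
        elif isinstance(value, tuple):
            fields.append(",".join(str(v) for v in value))
        else:
            fields.append(str(value))
    if variant.m:
        if len(record.custom) != variant.m:
            raise SerializationError(
                f"record has {len(record.custom)} custom fields, {variant} needs {variant.m}",
                code="MISSING_FIELD",
            )
        fields.extend(record.custom)
    sep = "\t" if delimiter == "tab" else " "
    if delimiter == "space" and any(" " in f for f in fields):
        raise SerializationError(
            "cannot space-delimit a record whose fields contain spaces",
            code="DELIMITER_CONFLICT",
        )
    return sep.join(fields)
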