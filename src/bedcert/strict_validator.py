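"""Strict, line-addressed validation of BED files.

Every rule failure is reported as a coded :class:`ValidationIssue`; the
file-level verdict is a pure function of the file bytes, the dialect and
the mode.  Warnings never flip the verdict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Union

from .bed_model import (
    BedVariant,
    Dialect,
    FLEXIBLE,
    VariantError,
    detect_variant,
)

__all__ = [
    "Code",
    "LINE_RULE_CODES",
    "ValidationIssue",
    "ValidationReport",
    "split_fields",
    "validate_line",
    "validate_file",
]


class Code:
    """Closed table of issue codes."""

    # file / line structure
    MALFORMED_FIELD_COUNT = "MALFORMED_FIELD_COUNT"
    PROHIBITED_VARIANT = "PROHIBITED_VARIANT"
    MIXED_FIELD_COUNT = "MIXED_FIELD_COUNT"
    MISSING_FIELD = "MISSING_FIELD"
    ENCODING = "ENCODING"
    # field rules, in field order
    CHROM_NAME = "CHROM_NAME"
    COORD_FORMAT = "COORD_FORMAT"
    NEGATIVE_COORD = "NEGATIVE_COORD"
    COORD_ORDER = "COORD_ORDER"
    NAME_INVALID = "NAME_INVALID"
    SCORE_FORMAT = "SCORE_FORMAT"
    SCORE_RANGE = "SCORE_RANGE"
    STRAND_SYMBOL = "STRAND_SYMBOL"
    THICK_FORMAT = "THICK_FORMAT"
    THICK_BOUNDS = "THICK_BOUNDS"
    RGB_FORMAT = "RGB_FORMAT"
    RGB_RANGE = "RGB_RANGE"
    BLOCK_COUNT = "BLOCK_COUNT"
    BLOCK_LIST_LENGTH = "BLOCK_LIST_LENGTH"
    BLOCK_SIZE = "BLOCK_SIZE"
    BLOCK_START = "BLOCK_START"
    BLOCK_ORDER = "BLOCK_ORDER"
    BLOCK_SPAN = "BLOCK_SPAN"
    # warnings (style, never errors)
    CRLF_LINE_ENDING = "CRLF_LINE_ENDING"


#: Codes that per-line field validation can emit (used by the corpus
#: coverage test).  MISSING_FIELD only arises in tabs-only dialects and
#: ENCODING only from undecodable bytes, so they are excluded here.
LINE_RULE_CODES = frozenset(
    {
        Code.MALFORMED_FIELD_COUNT,
        Code.PROHIBITED_VARIANT,
        Code.MIXED_FIELD_COUNT,
        Code.CHROM_NAME,
        Code.COORD_FORMAT,
        Code.NEGATIVE_COORD,
        Code.COORD_ORDER,
        Code.NAME_INVALID,
        Code.SCORE_FORMAT,
        Code.SCORE_RANGE,
        Code.STRAND_SYMBOL,
        Code.THICK_BOUNDS,
        Code.RGB_FORMAT,
        Code.RGB_RANGE,
        Code.BLOCK_COUNT,
        Code.BLOCK_LIST_LENGTH,
        Code.BLOCK_SIZE,
        Code.BLOCK_START,
        Code.BLOCK_ORDER,
        Code.BLOCK_SPAN,
    }
)

# chrom / name character sets: printable, no whitespace; chrom restricted
# to alphanumerics plus . _ - (covers chromosomes and scaffolds).
_CHROM_RE = re.compile(r"[A-Za-z0-9._-]{1,255}\Z")
_NAME_RE = re.compile(r"[\x21-\x7e]{1,255}\Z")
_UNSIGNED_RE = re.compile(r"[0-9]+\Z")
_SIGNED_RE = re.compile(r"-?[0-9]+\Z")
_WS_RE = re.compile(r"[ \t]+")


@dataclass(frozen=True)
class ValidationIssue:
    severity: Literal["error", "warning"]
    line_number: int
    field_index: Optional[int]  # 1-based, None for whole-line issues
    code: str
    message: str

    def __str__(self) -> str:
        fi = self.field_index if self.field_index is not None else "-"
        return f"{self.line_number}:{fi}:{self.code}: {self.message}"


@dataclass
class ValidationReport:
    path: str
    dialect: Dialect
    variant: Optional[BedVariant] = None
    record_count: int = 0
    blank_line_count: int = 0
    comment_line_count: int = 0
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "variant": str(self.variant) if self.variant else None,
            "record_count": self.record_count,
            "blank_line_count": self.blank_line_count,
            "comment_line_count": self.comment_line_count,
            "valid": self.valid,
            "issues": [
                {
                    "severity": i.severity,
                    "line": i.line_number,
                    "field": i.field_index,
                    "code": i.code,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }


def split_fields(line: str, dialect: Dialect = FLEXIBLE) -> List[str]:
    """Split one line into field texts; never fails.

    Tabs-only mode splits on every single tab, preserving empty fields
    for downstream rejection.  Flexible mode splits on maximal runs of
    tabs and spaces (so empty fields cannot occur) after trimming edge
    whitespace.
    """
    if dialect.whitespace == "tabs":
        return line.split("\t")
    stripped = line.strip(" \t")
    if not stripped:
        return []
    return _WS_RE.split(stripped)


def _err(line: int, fi: Optional[int], code: str, msg: str) -> ValidationIssue:
    return ValidationIssue("error", line, fi, code, msg)


def validate_line(
    fields: List[str],
    variant: BedVariant,
    strict: bool = True,
    line_number: int = 1,
) -> List[ValidationIssue]:
    """Apply the field rule table to one split line.

    Only the first ``variant.n`` fields are checked as standard BED
    fields; in custom (``strict=False``) interpretation the remaining
    ``variant.m`` fields may hold arbitrary text.  Returns an empty list
    iff every applicable rule passes.
    """
    issues: List[ValidationIssue] = []
    ln = line_number

    present = fields[: variant.n]
    missing = [i for i, f in enumerate(present) if f == ""]
    for i in missing:
        issues.append(
            _err(ln, i + 1, Code.MISSING_FIELD, "field is empty; all fields must contain values")
        )
    ok = [f != "" for f in present]

    def have(idx: int) -> bool:  # idx 0-based
        return idx < len(present) and ok[idx]

    # (1) chrom
    if have(0) and not _CHROM_RE.match(present[0]):
        issues.append(
            _err(ln, 1, Code.CHROM_NAME,
                 f"chrom {present[0]!r} must match [A-Za-z0-9._-]{{1,255}}")
        )

    # (2) coordinates
    coords: List[Optional[int]] = [None, None]
    for k, what in ((1, "chromStart"), (2, "chromEnd")):
        if not have(k):
            continue
        tok = present[k]
        if _UNSIGNED_RE.match(tok):
            coords[k - 1] = int(tok)
        elif _SIGNED_RE.match(tok):
            issues.append(
                _err(ln, k + 1, Code.NEGATIVE_COORD, f"{what} must be non-negative, got {tok!r}")
            )
        else:
            issues.append(
                _err(ln, k + 1, Code.COORD_FORMAT,
                     f"{what} must be an unsigned decimal integer, got {tok!r}")
            )
    start, end = coords
    if start is not None and end is not None and start > end:
        issues.append(
            _err(ln, 2, Code.COORD_ORDER, f"chromStart {start} exceeds chromEnd {end}")
        )

    # (3) name
    if have(3) and not _NAME_RE.match(present[3]):
        issues.append(
            _err(ln, 4, Code.NAME_INVALID,
                 f"name {present[3]!r} must be 1-255 printable non-whitespace characters")
        )

    # (4) score
    if have(4):
        tok = present[4]
        if not _SIGNED_RE.match(tok):
            issues.append(
                _err(ln, 5, Code.SCORE_FORMAT, f"score must be an integer, got {tok!r}")
            )
        elif not (0 <= int(tok) <= 1000):
            issues.append(
                _err(ln, 5, Code.SCORE_RANGE,
                     f"score must be between 0 and 1000 inclusive, got {tok!r}")
            )

    # (5) strand
    if have(5) and present[5] not in ("+", "-", "."):
        issues.append(
            _err(ln, 6, Code.STRAND_SYMBOL, f"strand must be '+', '-' or '.', got {present[5]!r}")
        )

    # (6) thickStart / thickEnd bounds
    thick: List[Optional[int]] = [None, None]
    for k, what in ((6, "thickStart"), (7, "thickEnd")):
        if not have(k):
            continue
        tok = present[k]
        if _UNSIGNED_RE.match(tok):
            thick[k - 6] = int(tok)
        else:
            issues.append(
                _err(ln, k + 1, Code.THICK_FORMAT,
                     f"{what} must be an unsigned decimal integer, got {tok!r}")
            )
    t_start, t_end = thick
    if t_start is not None:
        if start is not None and t_start < start:
            issues.append(
                _err(ln, 7, Code.THICK_BOUNDS,
                     f"thickStart {t_start} is less than chromStart {start}")
            )
        if t_end is None and end is not None and t_start > end:
            issues.append(
                _err(ln, 7, Code.THICK_BOUNDS,
                     f"thickStart {t_start} exceeds chromEnd {end}")
            )
    if t_end is not None:
        if t_start is not None and t_start > t_end:
            issues.append(
                _err(ln, 8, Code.THICK_BOUNDS,
                     f"thickStart {t_start} exceeds thickEnd {t_end}")
            )
        if end is not None and t_end > end:
            issues.append(
                _err(ln, 8, Code.THICK_BOUNDS,
                     f"thickEnd {t_end} exceeds chromEnd {end}")
            )

    # (7) itemRgb
    if have(8):
        tok = present[8]
        if tok != "0":
            parts = tok.split(",")
            if len(parts) != 3 or not all(_UNSIGNED_RE.match(p) for p in parts):
                issues.append(
                    _err(ln, 9, Code.RGB_FORMAT,
                         f"itemRgb must be '0' or an R,G,B triple, got {tok!r}")
                )
            elif any(int(p) > 255 for p in parts):
                issues.append(
                    _err(ln, 9, Code.RGB_RANGE,
                         f"itemRgb components must be 0-255, got {tok!r}")
                )

    # (8)-(10) blocks
    count: Optional[int] = None
    if have(9):
        tok = present[9]
        if not _UNSIGNED_RE.match(tok):
            issues.append(
                _err(ln, 10, Code.BLOCK_COUNT,
                     f"blockCount must be an unsigned decimal integer, got {tok!r}")
            )
        elif int(tok) < 1:
            issues.append(
                _err(ln, 10, Code.BLOCK_COUNT, f"blockCount must be at least 1, got {tok!r}")
            )
        else:
            count = int(tok)

    def parse_list(idx: int, label: str) -> Optional[List[int]]:
        tok = present[idx]
        body = tok[:-1] if tok.endswith(",") else tok  # one trailing comma tolerated
        parts = body.split(",") if body else []
        if not parts or not all(_SIGNED_RE.match(p) for p in parts):
            issues.append(
                _err(ln, idx + 1, Code.BLOCK_LIST_LENGTH,
                     f"{label} must be a comma-separated integer list, got {tok!r}")
            )
            return None
        values = [int(p) for p in parts]
        if count is not None and len(values) != count:
            issues.append(
                _err(ln, idx + 1, Code.BLOCK_LIST_LENGTH,
                     f"{label} has {len(values)} entries but blockCount is {count}")
            )
        return values

    sizes = parse_list(10, "blockSizes") if have(10) else None
    starts = parse_list(11, "blockStarts") if have(11) else None

    if sizes is not None and any(s < 1 for s in sizes):
        issues.append(
            _err(ln, 11, Code.BLOCK_SIZE, f"block sizes must be at least 1, got {present[10]!r}")
        )
    if starts is not None:
        if any(s < 0 for s in starts):
            issues.append(
                _err(ln, 12, Code.BLOCK_START,
                     f"block starts must be non-negative, got {present[11]!r}")
            )
        elif starts and starts[0] != 0:
            issues.append(
                _err(ln, 12, Code.BLOCK_START, f"first blockStart must be 0, got {starts[0]}")
            )
    if (
        sizes is not None
        and starts is not None
        and count is not None
        and len(sizes) == len(starts) == count
        and all(s >= 1 for s in sizes)
        and all(s >= 0 for s in starts)
    ):
        for i in range(1, count):
            if starts[i] < starts[i - 1] + sizes[i - 1]:
                issues.append(
                    _err(ln, 12, Code.BLOCK_ORDER,
                         f"block {i + 1} starts at {starts[i]} before block {i} "
                         f"ends at {starts[i - 1] + sizes[i - 1]}")
                )
                break
        if start is not None and end is not None and starts and starts[0] == 0:
            last_end = starts[-1] + sizes[-1]
            if last_end != end - start:
                issues.append(
                    _err(ln, 12, Code.BLOCK_SPAN,
                         f"last block ends at {last_end} but the interval spans {end - start}")
                )
    return issues


def _decode(data: bytes, issues: List[ValidationIssue]) -> str:
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError as exc:
        line = data[: exc.start].count(b"\n") + 1
        issues.append(
            _err(line, None, Code.ENCODING,
                 f"undecodable byte sequence at offset {exc.start}")
        )
        return data.decode("utf-8", errors="replace")


def validate_file(
    path: Union[str, Path],
    dialect: Dialect = FLEXIBLE,
    mode: Literal["strict", "custom"] = "strict",
    declared_variant: Optional[BedVariant] = None,
) -> ValidationReport:
    """Validate a whole BED file.

    Blank lines are permitted and counted, never errors.  The first data
    line fixes the file's variant; later lines with a different field
    count raise ``MIXED_FIELD_COUNT``.  ``report.valid`` is true iff no
    error-severity issue was found (warnings do not count).
    """
    path = Path(path)
    report = ValidationReport(path=str(path), dialect=dialect)
    data = path.read_bytes()
    text = _decode(data, report.issues)

    if "\r" in text:
        report.issues.append(
            ValidationIssue(
                "warning",
                text.split("\r", 1)[0].count("\n") + 1,
                None,
                Code.CRLF_LINE_ENDING,
                "carriage-return line endings found; LF is conventional",
            )
        )
        text = text.replace("\r\n", "\n").replace("\r", "\n")

    declared_n = declared_variant.n if declared_variant is not None else None
    fixed_count: Optional[int] = None
    for line_number, line in enumerate(text.split("\n"), start=1):
        if line.strip(" \t") == "":
            if line_number <= text.count("\n"):  # ignore the final empty split
                report.blank_line_count += 1
            continue
        if dialect.skip_comment_lines and (
            line.startswith("#") or line.startswith("track") or line.startswith("browser")
        ):
            report.comment_line_count += 1
            continue
        fields = split_fields(line, dialect)
        report.record_count += 1
        if fixed_count is None:
            fixed_count = len(fields)
            try:
                report.variant = detect_variant(len(fields), mode, declared_n)
            except VariantError as exc:
                report.issues.append(_err(line_number, None, exc.code, str(exc)))
                continue
        elif len(fields) != fixed_count:
            report.issues.append(
                _err(
                    line_number,
                    None,
                    Code.MIXED_FIELD_COUNT,
                    f"line has {len(fields)} fields but the file started with {fixed_count}",
                )
            )
            continue
        if report.variant is not None:
            report.issues.extend(
                validate_line(
                    fields, report.variant, strict=(mode == "strict"), line_number=line_number
                )
            )
    return report
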