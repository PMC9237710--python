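"""Deterministic conformance corpus: expected-pass and expected-fail BED
files for BED3 through BED12, plus minimal auxiliary fixtures.

The corpus has 92 cases.  Base cases are authored at the lowest variant
where the rule they exercise exists; "expandable" bases are then
repeated at every higher variant with neutral valid filler appended, so
later variants inherit the earlier rules.  Any case landing on BED10 or
BED11 is expected-fail regardless of its base expectation, because those
two field counts are prohibited as standard variants.

Genomic intervals stay between positions 250 000 and 260 000 (sensible
for both chromosomes and short scaffolds); expected-fail cases may
deliberately breach that floor (e.g. a negative start).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

from .bed_model import BedError, BedVariant

__all__ = [
    "COORD_FLOOR",
    "COORD_CEILING",
    "TestCase",
    "CorpusManifest",
    "ExpansionError",
    "base_cases",
    "expand_case",
    "build_corpus",
    "generate_corpus",
    "load_manifest",
    "make_minimal_fixtures",
]

COORD_FLOOR = 250_000
COORD_CEILING = 260_000

#: Variants the corpus covers, in file order (BED10/11 included, all-fail).
CORPUS_VARIANTS: Tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10, 11, 12)


class ExpansionError(BedError):
    code = "INVALID_EXPANSION"


@dataclass(frozen=True)
class TestCase:
    """One corpus file: its variant, expected verdict and content."""

    __test__ = False  # not a pytest class, despite the name

    identifier: str
    variant: BedVariant
    expectation: Literal["pass", "fail"]
    content: str
    provenance: str
    expandable: bool = False
    path: Optional[Path] = field(default=None, compare=False)

    @property
    def stem(self) -> str:
        return self.identifier.rsplit("/", 1)[-1]


@dataclass
class CorpusManifest:
    cases: List[TestCase]

    @property
    def total(self) -> int:
        return len(self.cases)

    def by_variant(self) -> Dict[BedVariant, List[TestCase]]:
        out: Dict[BedVariant, List[TestCase]] = {}
        for case in self.cases:
            out.setdefault(case.variant, []).append(case)
        return dict(sorted(out.items()))

    def counts(self) -> Dict[BedVariant, Tuple[int, int]]:
        """variant -> (expected-pass count, expected-fail count)."""
        out: Dict[BedVariant, Tuple[int, int]] = {}
        for variant, cases in self.by_variant().items():
            n_pass = sum(1 for c in cases if c.expectation == "pass")
            out[variant] = (n_pass, len(cases) - n_pass)
        return out


def _lines(*records: Tuple[str, ...]) -> str:
    return "".join("\t".join(r) + "\n" for r in records)


_R1 = ("chr1", "250000", "250500")
_R2 = ("chr7", "251000", "251700")
_R3 = ("GL000008.2", "252000", "252300")


def base_cases() -> List[TestCase]:
    """The hand-designed base cases, before upward expansion."""

    def case(n, stem, expectation, content, provenance, expandable=False):
        return TestCase(
            identifier=f"bed{n}/{stem}",
            variant=BedVariant(n),
            expectation=expectation,
            content=content,
            provenance=provenance,
            expandable=expandable,
        )

    long_name = "N" * 256
    cases = [
        # ---- BED3 ----
        case(3, "01-simple", "pass", _lines(_R1, _R2, _R3),
             "well-formed minimal intervals on chromosomes and a scaffold",
             expandable=True),
        case(3, "02-negative-start", "fail",
             _lines(_R1, ("chr1", "-1", "250100")),
             "chromStart must be non-negative", expandable=True),
        case(3, "03-start-after-end", "fail",
             _lines(_R1, ("chr1", "250500", "250000")),
             "chromStart must not exceed chromEnd", expandable=True),
        case(3, "04-non-numeric-start", "fail",
             _lines(_R1, ("chr1", "twelve", "250100")),
             "coordinates must be unsigned decimal integers"),
        case(3, "05-too-few-fields", "fail",
             "chr1\t250000\n",
             "a data line needs at least the 3 mandatory fields"),
        case(3, "06-too-many-fields", "fail",
             _lines(("chr1", "250000", "250500", "a", "500", "+", "250000",
                     "250500", "0", "1", "500", "0", "extra")),
             "a data line may have at most 12 standard fields"),
        case(3, "07-bad-chrom-character", "fail",
             _lines(("chr@1", "250000", "250100")),
             "chrom restricted to alphanumerics plus . _ -"),
        case(3, "08-mixed-field-count", "fail",
             _lines(_R1) + _lines(("chr1", "250600", "250700", "extra")),
             "all data lines of one file must share a field count"),
        case(3, "other-fully_space_delimited", "pass",
             "".join(" ".join(r) + "\n" for r in (_R1, _R2, _R3)),
             "space delimiters are allowed when fields contain no spaces"),
        case(3, "other-space_between_lines", "pass",
             _lines(_R1) + "\n" + _lines(_R2),
             "blank lines between records are permitted"),
        case(3, "other-zero_length_interval", "pass",
             _lines(("chr1", "250000", "250000")),
             "chromStart may equal chromEnd (zero-length interval)"),
        # ---- BED4 ----
        case(4, "04-name-too-long", "fail",
             _lines(_R1 + ("ok",), ("chr1", "250600", "250900", long_name)),
             "name is limited to 255 characters", expandable=True),
        # ---- BED5 ----
        case(5, "05-negative-score", "fail",
             _lines(_R1 + ("a", "500"), ("chr1", "250600", "250900", "b", "-5")),
             "score below the 0-1000 range", expandable=True),
        case(5, "06-non-integer-score", "fail",
             _lines(_R1 + ("a", "3.5")),
             "score must be an integer"),
        # ---- BED6 ----
        case(6, "06-strand-dot", "pass",
             _lines(_R1 + ("a", "500", "."), _R2 + ("b", "500", ".")),
             "strand '.' (unknown) is accepted on every record", expandable=True),
        case(6, "07-invalid-strand", "fail",
             _lines(_R1 + ("a", "500", "+"), ("chr1", "250600", "250900", "b", "500", "x")),
             "strand must be '+', '-' or '.'", expandable=True),
        # ---- BED7 ----
        case(7, "08-thick-start-low", "fail",
             _lines(_R1 + ("a", "500", "+", "250000"),
                    ("chr1", "250600", "250900", "b", "500", "+", "249990")),
             "thickStart must not precede chromStart", expandable=True),
        # ---- BED8 ----
        case(8, "09-thick-end-high", "fail",
             _lines(_R1 + ("a", "500", "+", "250000", "250500"),
                    ("chr1", "250600", "250900", "b", "500", "+", "250600", "250910")),
             "thickEnd must not exceed chromEnd", expandable=True),
        # ---- BED9 ----
        case(9, "10-rgb-out-of-range", "fail",
             _lines(_R1 + ("a", "500", "+", "250000", "250500", "255,128,0"),
                    ("chr1", "250600", "250900", "b", "500", "+", "250600", "250900", "256,0,0")),
             "itemRgb components limited to 0-255", expandable=True),
        case(9, "11-rgb-wrong-arity", "fail",
             _lines(_R1 + ("a", "500", "+", "250000", "250500", "255,0")),
             "itemRgb must be '0' or exactly three components"),
    ]

    # ---- BED12 block-structure locals ----
    def bed12(sizes: str, starts: str, count: str = "2") -> str:
        return _lines(("chr1", "250000", "250500", "a", "500", "+",
                       "250000", "250500", "0", count, sizes, starts))

    cases += [
        TestCase(f"bed12/{stem}", BedVariant(12), "fail", content, provenance)
        for stem, content, provenance in [
            ("11-block-count-zero", bed12("100", "0", count="0"),
             "blockCount must be at least 1"),
            ("12-block-list-length", bed12("100,200,50", "0,300"),
             "blockSizes longer than blockCount"),
            ("13-block-size-zero", bed12("0,200", "0,300"),
             "block sizes must be at least 1"),
            ("14-first-block-start-nonzero", bed12("100,200", "10,300"),
             "first blockStart must be 0"),
            ("15-blocks-overlap", bed12("100,450", "0,50"),
             "blocks must be ascending and non-overlapping"),
            ("16-last-block-short", bed12("100,150", "0,300"),
             "last block must end at chromEnd"),
        ]
    ]
    return cases


def _filler(start_tok: str, end_tok: str, stem: str, from_n: int, to_n: int) -> List[str]:
    """Neutral valid values for standard fields from_n+1 .. to_n."""
    try:
        span = int(end_tok) - int(start_tok)
    except ValueError:
        span = 100
    values = {
        4: stem,
        5: "500",
        6: "+",
        7: start_tok,
        8: end_tok,
        9: "0",
        10: "1",
        11: str(span),
        12: "0",
    }
    return [values[i] for i in range(from_n + 1, to_n + 1)]


def expand_case(base: TestCase, target: BedVariant) -> TestCase:
    """Repeat ``base`` at a higher variant by appending valid filler.

    The expectation is inherited, except that BED10/BED11 targets are
    always expected-fail.  ``expand_case(c, c.variant)`` is the identity.
    """
    if target.n < base.variant.n:
        raise ExpansionError(
            f"cannot expand {base.variant} case to lower variant {target}"
        )
    if target == base.variant:
        return base
    out_lines = []
    for line in base.content.splitlines():
        if line.strip(" \t") == "" or line.startswith("#"):
            out_lines.append(line)
            continue
        tokens = line.split("\t")
        start = tokens[1] if len(tokens) > 2 else "0"
        end = tokens[2] if len(tokens) > 2 else "100"
        tokens += _filler(start, end, base.stem, base.variant.n, target.n)
        out_lines.append("\t".join(tokens))
    expectation = "fail" if target.n in (10, 11) else base.expectation
    return replace(
        base,
        identifier=f"bed{target.n}/{base.stem}",
        variant=target,
        expectation=expectation,
        content="".join(l + "\n" for l in out_lines),
        expandable=False,
    )


def build_corpus() -> CorpusManifest:
    """Assemble all 92 cases (bases plus upward expansions), in memory."""
    cases: List[TestCase] = []
    for base in base_cases():
        cases.append(base)
        if base.expandable:
            for n in CORPUS_VARIANTS:
                if n > base.variant.n:
                    cases.append(expand_case(base, BedVariant(n)))
    cases.sort(key=lambda c: (c.variant.n, c.stem))
    return CorpusManifest(cases)


def generate_corpus(out_dir: Union[str, Path]) -> CorpusManifest:
    """Write the corpus tree and manifest under ``out_dir``.

    Layout: ``<out>/bed{n}/{expected_pass|expected_fail}/<case>.bed`` plus
    ``manifest.tsv``.  Generation involves no randomness: two runs
    produce byte-identical trees.
    """
    out_dir = Path(out_dir)
    manifest = build_corpus()
    placed: List[TestCase] = []
    for case in manifest.cases:
        sub = "expected_pass" if case.expectation == "pass" else "expected_fail"
        path = out_dir / f"bed{case.variant.n}" / sub / f"{case.stem}.bed"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(case.content, newline="")
        placed.append(replace(case, path=path))
    manifest.cases = placed
    with open(out_dir / "manifest.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["identifier", "variant", "expectation", "path", "provenance"])
        for case in placed:
            writer.writerow(
                [case.identifier, str(case.variant), case.expectation,
                 str(case.path.relative_to(out_dir)), case.provenance]
            )
    return manifest


def load_manifest(corpus_dir: Union[str, Path]) -> CorpusManifest:
    """Read back a corpus written by :func:`generate_corpus`."""
    corpus_dir = Path(corpus_dir)
    cases: List[TestCase] = []
    with open(corpus_dir / "manifest.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            n_part, _, m_part = row["variant"][3:].partition("+")
            path = corpus_dir / row["path"]
            cases.append(
                TestCase(
                    identifier=row["identifier"],
                    variant=BedVariant(int(n_part), int(m_part or 0)),
                    expectation=row["expectation"],  # type: ignore[arg-type]
                    content=path.read_text(),
                    provenance=row["provenance"],
                    path=path,
                )
            )
    return CorpusManifest(cases)


#: Mock assembly used by the auxiliary fixtures.
_FIXTURE_CHROMS = (("chr1", 300_000), ("chr7", 280_000))


def make_minimal_fixtures(out_dir: Union[str, Path]) -> List[Path]:
    """Write a small FASTA and a chrom-sizes file matching the corpus range.

    Sequences deterministically tile ACGT out to beyond position 260 000
    so secondary-input tools see coherent coordinates.  Returns the paths
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "mock_assembly.fa"
    sizes = out_dir / "mock_assembly.chrom.sizes"
    with open(fasta, "w", newline="") as fh:
        for name, length in _FIXTURE_CHROMS:
            fh.write(f">{name}\n")
            seq = ("ACGT" * (length // 4 + 1))[:length]
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(sizes, "w", newline="") as fh:
        for name, length in _FIXTURE_CHROMS:
            fh.write(f"{name}\t{length}\n")
    return [fasta, sizes]
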