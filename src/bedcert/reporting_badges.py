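"""Percentages, summary tables and SVG badges from harness results.

A "BED parser" badge advertises which variants a tool supports; one
performance badge per scored variant shows the percentage of corpus
cases that behaved as expected, formatted to one decimal with half-up
rounding (0.78787... renders as "78.8%").
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .bed_model import BedVariant
from .conformance_harness import VariantScore, score_by_variant

__all__ = [
    "COLOR_THRESHOLDS",
    "BadgeDescriptor",
    "format_percentage",
    "make_badges",
    "summary_table",
    "write_summary",
]

# Bucketed badge colors (proportion floor -> hex); plumbing, configurable.
COLOR_THRESHOLDS = ((0.9, "#4c1"), (0.7, "#dfb317"), (0.0, "#e05d44"))

_LABEL_COLOR = "#555"
_PARSER_COLOR = "#007ec6"


@dataclass(frozen=True)
class BadgeDescriptor:
    label: str
    value: str
    color: str
    svg: str


def format_percentage(proportion: float) -> str:
    """One-decimal percentage with a ``%`` suffix, rounded half-up."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    pct = (Decimal(repr(proportion)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{pct}%"


def _bucket_color(proportion: float) -> str:
    for floor, color in COLOR_THRESHOLDS:
        if proportion >= floor:
            return color
    return COLOR_THRESHOLDS[-1][1]


def _render_svg(label: str, value: str, color: str) -> str:
    # Flat two-segment badge; widths estimated at ~6.5 px per character.
    lw = int(len(label) * 6.5) + 10
    vw = int(len(value) * 6.5) + 10
    total = lw + vw
    return f"""<svg xmlns="http://www.w3.org/2000/svg" width="{total}" height="20" role="img" aria-label="{label}: {value}">
  <rect width="{lw}" height="20" fill="{_LABEL_COLOR}"/>
  <rect x="{lw}" width="{vw}" height="20" fill="{color}"/>
  <g fill="#fff" text-anchor="middle" font-family="Verdana,Geneva,DejaVu Sans,sans-serif" font-size="11">
    <text x="{lw / 2}" y="14">{label}</text>
    <text x="{lw + vw / 2}" y="14">{value}</text>
  </g>
</svg>
"""


def _variant_list_text(variants: Sequence[BedVariant]) -> str:
    return ", ".join(str(v) for v in sorted(variants)) if variants else "none"


def make_badges(
    scores: Iterable[VariantScore],
    supported: Sequence[BedVariant],
    out_dir: Optional[Union[str, Path]] = None,
) -> List[BadgeDescriptor]:
    """One "BED parser" badge plus one performance badge per score.

    Rendering is a deterministic function of the inputs; files are
    written only when ``out_dir`` is given.
    """
    badges = [
        BadgeDescriptor(
            label="BED parser",
            value=_variant_list_text(supported),
            color=_PARSER_COLOR,
            svg=_render_svg("BED parser", _variant_list_text(supported), _PARSER_COLOR),
        )
    ]
    for score in scores:
        label = str(score.variant)
        value = format_percentage(score.proportion)
        color = _bucket_color(score.proportion)
        badges.append(BadgeDescriptor(label, value, color, _render_svg(label, value, color)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for badge in badges:
            name = badge.label.replace(" ", "_").lower() + ".svg"
            (out_dir / name).write_text(badge.svg)
    return badges


def _variant_sort_key(label: str):
    n_part, _, m_part = label[3:].partition("+")
    return int(n_part), int(m_part or 0)


def summary_table(matrices: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-tool, per-variant proportions of expected behavior.

    Rows are tools sorted ascending by their proportion on BED3, then on
    each subsequent variant; columns are variants in field-count order.
    """
    records = {}
    for tool, matrix in matrices.items():
        records[tool] = {
            str(s.variant): s.proportion for s in score_by_variant(matrix)
        }
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame = frame[sorted(frame.columns, key=_variant_sort_key)]
    frame = frame.sort_values(by=list(frame.columns), ascending=True)
    frame.index.name = "tool"
    return frame


def write_summary(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6f")
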