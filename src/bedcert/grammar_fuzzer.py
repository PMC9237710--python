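"""Grammar-based BED fuzzing and differential testing.

A *meta-grammar* is sampled into a concrete :class:`GrammarInstance`: a
seeded choice of dialect (tabs only, or tabs and spaces; blank lines;
comment lines), a BED variant, and per-field value generators.
``strictly-valid`` instances only emit content the strict validator
accepts under the matching dialect; ``possibly-invalid`` instances
mutate exactly one rule away from the format rules, so any discordance
two consumers show on the generated file is attributable to that rule.

The grammar engine is a seeded recursive generator over an internal rule
representation; no external parser-generator toolchain is involved.
"""

from __future__ import annotations

import random
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Literal, Optional, Tuple

from .bed_model import BedVariant, Dialect, standard_variants
from .conformance_harness import (
    ToolMissingError,
    ToolSpec,
    classify_outcome,
    run_tool_on_case,
    tool_available,
)
from .corpus_generator import TestCase

__all__ = [
    "MUTATIONS",
    "GrammarInstance",
    "Discordance",
    "DiscordanceReport",
    "instantiate_grammar",
    "generate_line",
    "generate_file",
    "differential_run",
]

_CHROM_POOL = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y", "M"]) + (
    "GL000008.2",
    "KI270757.1",
)
_NAME_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789._-"
)

#: Single-rule deviations a possibly-invalid grammar may carry.
MUTATIONS: Tuple[str, ...] = (
    "score-out-of-range",
    "negative-start",
    "start-after-end",
    "bad-strand",
    "rgb-out-of-range",
    "prohibited-variant",
)


@dataclass(frozen=True)
class GrammarInstance:
    """One concrete BED grammar sampled from the meta-grammar."""

    seed: int
    validity: Literal["strictly-valid", "possibly-invalid"]
    variant: BedVariant
    delimiters: Tuple[str, ...]  # ("\t",) or ("\t", " ")
    blank_lines: bool
    comment_lines: bool
    coord_low: int = 0
    coord_high: int = 1_000_000
    max_interval: int = 10_000
    mutation: Optional[str] = None

    @property
    def dialect(self) -> Dialect:
        return Dialect(
            whitespace="tabs" if self.delimiters == ("\t",) else "flexible",
            allow_blank_lines=True,
            skip_comment_lines=self.comment_lines,
        )

    def key(self) -> str:
        return (
            f"{self.validity}|{self.variant}|{''.join(self.delimiters)!r}|"
            f"{self.blank_lines}|{self.comment_lines}|{self.mutation}"
        )


def instantiate_grammar(
    seed: int,
    validity: Literal["strictly-valid", "possibly-invalid"] = "strictly-valid",
) -> GrammarInstance:
    """Sample the meta-grammar; deterministic in ``seed``."""
    rng = random.Random(f"meta:{seed}")
    variant = rng.choice(standard_variants())
    delimiters = rng.choice((("\t",), ("\t", " ")))
    instance = GrammarInstance(
        seed=seed,
        validity=validity,
        variant=variant,
        delimiters=delimiters,
        blank_lines=rng.random() < 0.5,
        comment_lines=rng.random() < 0.5,
    )
    if validity == "possibly-invalid":
        mutation = rng.choice(MUTATIONS)
        if mutation == "prohibited-variant":
            instance = replace(instance, variant=BedVariant(rng.choice((10, 11))))
        instance = replace(instance, mutation=mutation)
    return instance


def _valid_fields(rng: random.Random, grammar: GrammarInstance) -> List[str]:
    n = grammar.variant.n
    start = rng.randrange(grammar.coord_low, grammar.coord_high)
    end = start + rng.randrange(1, grammar.max_interval)
    fields = [rng.choice(_CHROM_POOL), str(start), str(end)]
    if n >= 4:
        fields.append("".join(rng.choice(_NAME_ALPHABET) for _ in range(rng.randrange(1, 12))))
    if n >= 5:
        fields.append(str(rng.randrange(0, 1001)))
    if n >= 6:
        fields.append(rng.choice("+-."))
    if n >= 7:
        t_start = rng.randrange(start, end + 1)
        fields.append(str(t_start))
    if n >= 8:
        fields.append(str(rng.randrange(int(fields[6]), end + 1)))
    if n >= 9:
        fields.append(
            "0" if rng.random() < 0.5
            else ",".join(str(rng.randrange(0, 256)) for _ in range(3))
        )
    if n >= 10:
        # Blocks tiling part of the interval: ascending, non-overlapping,
        # first start 0, last block ending at end - start.
        span = end - start
        max_count = min(4, (span + 1) // 2)
        count = rng.randrange(1, max_count + 1)
        cuts = sorted(rng.sample(range(1, span), 2 * count - 2)) if count > 1 else []
        bounds = [0] + cuts + [span]
        starts = [bounds[2 * i] for i in range(count)]
        sizes = [bounds[2 * i + 1] - bounds[2 * i] for i in range(count)]
        fields.append(str(count))
        if n >= 11:
            fields.append(",".join(str(s) for s in sizes))
        if n >= 12:
            fields.append(",".join(str(s) for s in starts))
    return fields


def _mutate(fields: List[str], rng: random.Random, grammar: GrammarInstance) -> List[str]:
    mutation = grammar.mutation
    n = grammar.variant.n
    if mutation == "score-out-of-range" and n >= 5:
        fields[4] = str(rng.choice((-rng.randrange(1, 100), rng.randrange(1001, 2001))))
    elif mutation == "negative-start":
        fields[1] = str(-rng.randrange(1, 1000))
    elif mutation == "start-after-end":
        fields[1] = str(int(fields[2]) + rng.randrange(1, 100))
    elif mutation == "bad-strand" and n >= 6:
        fields[5] = rng.choice("*?x")
    elif mutation == "rgb-out-of-range" and n >= 9:
        fields[8] = f"{rng.randrange(256, 1000)},0,0"
    return fields


def generate_line(grammar: GrammarInstance, rng: random.Random) -> str:
    fields = _valid_fields(rng, grammar)
    if grammar.validity == "possibly-invalid" and grammar.mutation != "prohibited-variant":
        # Mutate roughly half the lines so both verdict classes occur.
        if rng.random() < 0.5:
            fields = _mutate(fields, rng, grammar)
    sep = lambda: rng.choice(grammar.delimiters)  # noqa: E731
    out = fields[0]
    for f in fields[1:]:
        out += sep() + f
    return out


def generate_file(grammar: GrammarInstance, seed: int, n_lines: int) -> str:
    """Emit ``n_lines`` data lines (plus any blank/comment lines the
    grammar allows); byte-identical for identical ``(grammar, seed)``."""
    rng = random.Random(f"file:{grammar.key()}:{seed}")
    lines: List[str] = []
    for _ in range(n_lines):
        if grammar.comment_lines and rng.random() < 0.2:
            lines.append("#" + "".join(rng.choice(_NAME_ALPHABET + "_") for _ in range(rng.randrange(1, 4))))
        if grammar.blank_lines and lines and rng.random() < 0.2:
            lines.append("")
        lines.append(generate_line(grammar, rng))
    if n_lines == 0 and grammar.comment_lines:
        lines.append("#empty")
    return "".join(line + "\n" for line in lines)


@dataclass(frozen=True)
class Discordance:
    trial: int
    grammar_key: str
    content: str
    verdict_a: str
    verdict_b: str


@dataclass
class DiscordanceReport:
    tool_a: str
    tool_b: str
    trial_count: int
    discordances: List[Discordance] = field(default_factory=list)


def differential_run(
    tool_a: ToolSpec,
    tool_b: ToolSpec,
    n_trials: int,
    seed: int,
    validity: Literal["strictly-valid", "possibly-invalid"] = "possibly-invalid",
    work_dir: Optional[Path] = None,
    timeout: float = 30,
) -> DiscordanceReport:
    """Run both tools on freshly generated files and record disagreements.

    Each trial samples a new grammar instance and file.  Verdicts come
    from :func:`bedcert.conformance_harness.classify_outcome`; every
    recorded discordance keeps the full file content for triage.  The
    report is a deterministic function of (tools, n_trials, seed).
    """
    for tool in (tool_a, tool_b):
        if not tool_available(tool):
            raise ToolMissingError(f"tool {tool.name!r} not runnable: {tool.executable}")
    rng = random.Random(f"diff:{seed}")
    report = DiscordanceReport(tool_a.name, tool_b.name, n_trials)
    with tempfile.TemporaryDirectory(dir=work_dir, prefix="bedcert-fuzz-") as tmp:
        for trial in range(n_trials):
            trial_seed = rng.randrange(2**32)
            grammar = instantiate_grammar(trial_seed, validity)
            content = generate_file(grammar, trial_seed, n_lines=rng.randrange(1, 6))
            path = Path(tmp) / f"trial-{trial}.bed"
            path.write_text(content, newline="")
            case = TestCase(
                identifier=f"trial-{trial}",
                variant=grammar.variant,
                expectation="pass",
                content=content,
                provenance=grammar.key(),
                path=path,
            )
            verdict_a = classify_outcome(
                run_tool_on_case(tool_a, case, timeout=timeout), tool_a.patterns
            )
            verdict_b = classify_outcome(
                run_tool_on_case(tool_b, case, timeout=timeout), tool_b.patterns
            )
            if verdict_a != verdict_b:
                report.discordances.append(
                    Discordance(trial, grammar.key(), content, verdict_a, verdict_b)
                )
    return report
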