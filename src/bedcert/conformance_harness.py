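"""Run external command-line tools over the conformance corpus and score
how often they behave as expected.

A tool's verdict on one file is classified from its exit status and its
captured standard output and error: it *passes* iff the exit status is
zero, no configured error/warning pattern appears in either stream, and
the run did not time out.  A case "behaved as expected" when the
classified verdict matches the case's expectation.
"""

from __future__ import annotations

import logging
import shlex
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .bed_model import BedError, BedVariant
from .corpus_generator import CorpusManifest, TestCase

__all__ = [
    "DEFAULT_PATTERNS",
    "ConfigError",
    "ToolMissingError",
    "ToolSpec",
    "ToolOutcome",
    "VariantScore",
    "load_config",
    "tool_available",
    "run_tool_on_case",
    "classify_outcome",
    "evaluate",
    "score_by_variant",
]

logger = logging.getLogger(__name__)

#: Case-insensitive substrings scanned in stdout/stderr unless a tool
#: overrides them.  Identifying messages is configuration, not code.
DEFAULT_PATTERNS: Tuple[str, ...] = ("error", "warning", "exception", "traceback")

DEFAULT_TIMEOUT = 60  # seconds per case


class ConfigError(BedError):
    code = "CONFIG_ERROR"


class ToolMissingError(BedError):
    code = "TOOL_MISSING"


@dataclass(frozen=True)
class ToolSpec:
    """How to invoke one tool; ``template`` holds the literal ``FILE``
    placeholder exactly once."""

    name: str
    template: str
    environment: Optional[str] = None
    patterns: Tuple[str, ...] = DEFAULT_PATTERNS

    def __post_init__(self) -> None:
        if self.template.count("FILE") != 1:
            raise ConfigError(
                f"tool {self.name!r}: template must contain 'FILE' exactly once: "
                f"{self.template!r}"
            )

    def command_for(self, bed_path: Union[str, Path]) -> str:
        return self.template.replace("FILE", str(bed_path))

    @property
    def executable(self) -> str:
        return shlex.split(self.template)[0]


@dataclass(frozen=True)
class ToolOutcome:
    case_id: str
    exit_status: int
    stdout: str
    stderr: str
    timed_out: bool = False
    missing: bool = False


@dataclass(frozen=True)
class VariantScore:
    variant: BedVariant
    expected_count: int
    total_count: int

    @property
    def proportion(self) -> float:
        return self.expected_count / self.total_count


def _substitute_settings(template: str, settings: Mapping[str, str]) -> str:
    for key, value in settings.items():
        template = template.replace(key, str(value))
    return template


def load_config(path: Union[str, Path]) -> Tuple[List[ToolSpec], Dict[str, str]]:
    """Parse the YAML configuration.

    Three sections are recognized: ``settings`` (named placeholders
    resolved into templates), ``tools`` (name -> invocation template
    containing ``FILE``) and ``conda-environment`` (name -> environment
    label).  Returns the tool specs and the resolved settings map.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "tools" not in doc:
        raise ConfigError(f"{path}: configuration must contain a 'tools' section")
    settings = dict(doc.get("settings") or {})
    environments = dict(doc.get("conda-environment") or {})
    patterns = doc.get("patterns") or {}

    raw_tools = doc["tools"]
    if isinstance(raw_tools, list):  # list of single-entry maps is also accepted
        merged: Dict[str, str] = {}
        for entry in raw_tools:
            merged.update(entry)
        raw_tools = merged
    tools = []
    for name, template in raw_tools.items():
        if not isinstance(template, str):
            raise ConfigError(f"tool {name!r}: invocation template must be text")
        tools.append(
            ToolSpec(
                name=name,
                template=_substitute_settings(template, settings),
                environment=environments.get(name),
                patterns=tuple(patterns.get(name, DEFAULT_PATTERNS)),
            )
        )
    return tools, settings


def environment_prefix(label: Optional[str]) -> str:
    """Command prefix activating the tool's isolated environment.

    If no environment manager is available the label is ignored with a
    notice, which keeps the harness runnable with mock tools.
    """
    if not label:
        return ""
    for manager in ("conda", "micromamba", "mamba"):
        if shutil.which(manager):
            return f"{manager} run -n {shlex.quote(label)} "
    logger.info("no environment manager found; ignoring environment %r", label)
    return ""


def tool_available(tool: ToolSpec) -> bool:
    exe = tool.executable
    return Path(exe).exists() or shutil.which(exe) is not None


def run_tool_on_case(
    tool: ToolSpec,
    case: TestCase,
    timeout: float = DEFAULT_TIMEOUT,
) -> ToolOutcome:
    """Run one tool on one corpus file, capturing both streams.

    A missing executable is recorded (``missing=True``), not fatal; a
    timeout marks ``timed_out=True`` and later classifies as fail.
    """
    if case.path is None:
        raise ValueError(f"case {case.identifier} has no on-disk path")
    if not tool_available(tool):
        return ToolOutcome(case.identifier, 127, "", f"{tool.executable}: not found",
                           missing=True)
    command = environment_prefix(tool.environment) + tool.command_for(case.path)
    try:
        proc = subprocess.run(
            command, shell=True, capture_output=True, text=True, timeout=timeout
        )
        return ToolOutcome(case.identifier, proc.returncode, proc.stdout, proc.stderr)
    except subprocess.TimeoutExpired as exc:
        out = exc.stdout.decode() if isinstance(exc.stdout, bytes) else (exc.stdout or "")
        err = exc.stderr.decode() if isinstance(exc.stderr, bytes) else (exc.stderr or "")
        return ToolOutcome(case.identifier, -1, out, err, timed_out=True)


def classify_outcome(
    outcome: ToolOutcome, patterns: Sequence[str] = DEFAULT_PATTERNS
) -> Literal["pass", "fail"]:
    """Pure classification: pass iff exit 0, no pattern match, no timeout."""
    if outcome.timed_out or outcome.missing or outcome.exit_status != 0:
        return "fail"
    haystack = (outcome.stdout + "\n" + outcome.stderr).lower()
    if any(p.lower() in haystack for p in patterns):
        return "fail"
    return "pass"


def evaluate(
    tool: ToolSpec,
    manifest: CorpusManifest,
    timeout: float = DEFAULT_TIMEOUT,
) -> pd.DataFrame:
    """Run ``tool`` over every case of the corpus.

    Returns one row per case with columns ``tool, case, variant,
    expectation, classified, behaved_as_expected``.  If the executable is
    missing, an empty frame flagged ``missing`` is returned so the sweep
    over other tools can continue.
    """
    columns = ["tool", "case", "variant", "expectation", "classified",
               "behaved_as_expected"]
    if not tool_available(tool):
        logger.warning("tool %s not found (%s); skipping", tool.name, tool.executable)
        frame = pd.DataFrame(columns=columns)
        frame.attrs["missing"] = True
        return frame
    rows = []
    for case in manifest.cases:
        outcome = run_tool_on_case(tool, case, timeout=timeout)
        verdict = classify_outcome(outcome, tool.patterns)
        rows.append(
            {
                "tool": tool.name,
                "case": case.identifier,
                "variant": str(case.variant),
                "expectation": case.expectation,
                "classified": verdict,
                "behaved_as_expected": verdict == case.expectation,
            }
        )
    frame = pd.DataFrame(rows, columns=columns)
    frame.attrs["missing"] = False
    return frame


def _variant_key(label: str) -> Tuple[int, int]:
    n_part, _, m_part = label[3:].partition("+")
    return int(n_part), int(m_part or 0)


def score_by_variant(matrix: pd.DataFrame) -> List[VariantScore]:
    """Per-variant proportion of cases that behaved as expected."""
    scores = []
    for label, group in matrix.groupby("variant", sort=False):
        n, m = _variant_key(str(label))
        scores.append(
            VariantScore(
                variant=BedVariant(n, m),
                expected_count=int(group["behaved_as_expected"].sum()),
                total_count=len(group),
            )
        )
    scores.sort(key=lambda s: (s.variant.n, s.variant.m))
    return scores
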