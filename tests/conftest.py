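import sys
import textwrap
from pathlib import Path

import pytest

from bedcert.conformance_harness import ToolSpec
from bedcert.corpus_generator import generate_corpus

_MOCK_SOURCES = {
    "accept_all": """
        import sys
        open(sys.argv[1]).read()
        sys.exit(0)
    """,
    "reject_all": """
        import sys
        print("Error: input rejected", file=sys.stderr)
        sys.exit(1)
    """,
    "warn_only": """
        import sys
        print("Warning: skipped line 3", file=sys.stderr)
        sys.exit(0)
    """,
    "reject_4_fields": """
        import re, sys
        for line in open(sys.argv[1]):
            line = line.rstrip("\\n")
            if not line.strip() or line.startswith("#"):
                continue
            if len(re.split(r"[ \\t]+", line.strip())) == 4:
                print("Error: a line has 4 fields, but 0 were expected", file=sys.stderr)
                sys.exit(1)
        sys.exit(0)
    """,
    "sleeper": """
        import time
        time.sleep(30)
    """,
}


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("corpus")
    generate_corpus(out)
    return out


@pytest.fixture(scope="session")
def corpus_manifest(corpus_dir):
    from bedcert.corpus_generator import load_manifest

    return load_manifest(corpus_dir)


@pytest.fixture(scope="session")
def mock_tools(tmp_path_factory):
    """Tiny deterministic command-line tools as ToolSpecs."""
    bin_dir = tmp_path_factory.mktemp("mock-tools")
    tools = {}
    for name, source in _MOCK_SOURCES.items():
        script = bin_dir / f"{name}.py"
        script.write_text(textwrap.dedent(source).lstrip())
        tools[name] = ToolSpec(
            name=name, template=f'"{sys.executable}" "{script}" FILE'
        )
    return tools


@pytest.fixture(scope="session")
def validator_tool():
    """The package's own CLI as a tool under test."""
    return ToolSpec(
        name="bedcert-validate",
        template=f'"{sys.executable}" -m bedcert validate FILE',
    )
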