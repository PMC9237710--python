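import filecmp
import re
from pathlib import Path

import pytest

from bedcert.bed_model import BedVariant, FLEXIBLE
from bedcert.corpus_generator import (
    COORD_CEILING,
    COORD_FLOOR,
    ExpansionError,
    TestCase,
    build_corpus,
    expand_case,
    generate_corpus,
    load_manifest,
    make_minimal_fixtures,
)
from bedcert.strict_validator import LINE_RULE_CODES, validate_file


def _tree_bytes(root: Path) -> dict:
    return {
        p.relative_to(root): p.read_bytes()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestCorpusShape:
    def test_total_is_92(self, corpus_manifest):
        assert corpus_manifest.total == 92

    def test_identifiers_unique(self, corpus_manifest):
        ids = [c.identifier for c in corpus_manifest.cases]
        assert len(set(ids)) == len(ids)

    def test_counts_sum_to_total(self, corpus_manifest):
        counts = corpus_manifest.counts()
        assert sum(p + f for p, f in counts.values()) == corpus_manifest.total

    @pytest.mark.parametrize("n", [10, 11])
    def test_bed10_bed11_have_zero_expected_pass(self, corpus_manifest, n):
        n_pass, n_fail = corpus_manifest.counts()[BedVariant(n)]
        assert n_pass == 0
        assert n_fail > 0

    def test_all_ten_variants_covered(self, corpus_manifest):
        assert sorted(v.n for v in corpus_manifest.counts()) == list(range(3, 13))

    def test_coordinates_within_declared_range(self, corpus_manifest):
        # Fail cases may breach the floor on purpose (negative starts),
        # but nothing in the corpus exceeds the ceiling, and expected-pass
        # coordinates stay within [250000, 260000].
        coord_re = re.compile(r"\b(\d{4,})\b")
        max_seen = 0
        for case in corpus_manifest.cases:
            for match in coord_re.finditer(case.content):
                value = int(match.group(1))
                max_seen = max(max_seen, value)
                if case.expectation == "pass":
                    assert COORD_FLOOR <= value <= COORD_CEILING, case.identifier
        assert max_seen <= COORD_CEILING


class TestSelfConformance:
    def test_every_case_behaves_as_labeled(self, corpus_manifest):
        for case in corpus_manifest.cases:
            report = validate_file(case.path, dialect=FLEXIBLE)
            if case.expectation == "pass":
                assert report.valid and not report.issues, (
                    case.identifier,
                    [str(i) for i in report.issues],
                )
            else:
                assert report.errors, case.identifier

    def test_every_rule_code_exercised_by_a_fail_case(self, corpus_manifest):
        seen = set()
        for case in corpus_manifest.cases:
            if case.expectation == "fail":
                report = validate_file(case.path, dialect=FLEXIBLE)
                seen.update(i.code for i in report.errors)
        assert LINE_RULE_CODES <= seen


class TestExpandCase:
    def base(self):
        return TestCase(
            identifier="bed5/05-negative-score",
            variant=BedVariant(5),
            expectation="fail",
            content="chr1\t250000\t250100\ta\t-5\n",
            provenance="negative score",
        )

    def test_identity_expansion(self):
        case = self.base()
        assert expand_case(case, case.variant) is case

    def test_failing_base_stays_failing_up_to_bed12(self):
        expanded = expand_case(self.base(), BedVariant(12))
        assert expanded.expectation == "fail"
        assert expanded.content.count("\t") == 11
        report_fields = expanded.content.strip().split("\t")
        assert report_fields[4] == "-5"  # the deviation is preserved

    @pytest.mark.parametrize("n", [10, 11])
    def test_any_expansion_to_bed10_bed11_fails(self, n):
        passing = TestCase(
            identifier="bed3/01-simple",
            variant=BedVariant(3),
            expectation="pass",
            content="chr1\t250000\t250100\n",
            provenance="valid",
        )
        assert expand_case(passing, BedVariant(n)).expectation == "fail"

    def test_downward_expansion_rejected(self):
        with pytest.raises(ExpansionError) as exc:
            expand_case(self.base(), BedVariant(3))
        assert exc.value.code == "INVALID_EXPANSION"

    def test_filler_is_valid(self):
        passing = TestCase(
            identifier="bed3/01-simple",
            variant=BedVariant(3),
            expectation="pass",
            content="chr1\t250000\t250100\n",
            provenance="valid",
        )
        expanded = expand_case(passing, BedVariant(12))
        from bedcert.strict_validator import split_fields, validate_line

        fields = split_fields(expanded.content.strip())
        assert validate_line(fields, BedVariant(12)) == []


class TestDeterminism:
    def test_two_runs_are_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_corpus(a)
        generate_corpus(b)
        assert _tree_bytes(a) == _tree_bytes(b)

    def test_manifest_round_trip(self, corpus_dir, corpus_manifest):
        reloaded = load_manifest(corpus_dir)
        assert [c.identifier for c in reloaded.cases] == [
            c.identifier for c in corpus_manifest.cases
        ]
        assert all(
            a.content == b.content
            for a, b in zip(reloaded.cases, corpus_manifest.cases)
        )

    def test_in_memory_matches_on_disk(self, corpus_manifest):
        in_memory = build_corpus()
        assert [c.identifier for c in in_memory.cases] == [
            c.identifier for c in corpus_manifest.cases
        ]


class TestFixtures:
    def test_fixture_contract(self, tmp_path):
        paths = make_minimal_fixtures(tmp_path)
        fasta, sizes = paths
        headers = [l for l in fasta.read_text().splitlines() if l.startswith(">")]
        size_rows = [l.split("\t") for l in sizes.read_text().splitlines()]
        assert len(headers) == len(size_rows)
        for _, length in size_rows:
            assert int(length) >= COORD_CEILING
        # sequence lengths match the declared sizes
        seqs, current = {}, None
        for line in fasta.read_text().splitlines():
            if line.startswith(">"):
                current = line[1:]
                seqs[current] = 0
            else:
                seqs[current] += len(line)
        assert seqs == {name: int(length) for name, length in size_rows}

    def test_fixture_determinism(self, tmp_path):
        make_minimal_fixtures(tmp_path / "x")
        make_minimal_fixtures(tmp_path / "y")
        assert filecmp.cmp(
            tmp_path / "x/mock_assembly.fa", tmp_path / "y/mock_assembly.fa",
            shallow=False,
        )
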