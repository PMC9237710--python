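import subprocess
import sys

import pytest

from bedcert.bed_model import BedVariant, Dialect, FLEXIBLE, TABS
from bedcert.strict_validator import (
    Code,
    split_fields,
    validate_file,
    validate_line,
)

BED5 = BedVariant(5)
BED3 = BedVariant(3)


def codes(issues):
    return [i.code for i in issues]


class TestSplitFields:
    def test_tab_delimited_four_fields(self):
        assert split_fields("chr12\t632184\t753365\tVx6", TABS) == [
            "chr12", "632184", "753365", "Vx6",
        ]

    def test_three_tokens(self):
        assert split_fields("chr1\t250000\t250100", TABS) == ["chr1", "250000", "250100"]

    def test_dialects_disagree_on_embedded_space(self):
        assert split_fields("a b\tc", TABS) == ["a b", "c"]
        assert split_fields("a b\tc", FLEXIBLE) == ["a", "b", "c"]

    def test_tabs_mode_preserves_empty_fields(self):
        assert split_fields("a\t\tb", TABS) == ["a", "", "b"]

    def test_flexible_collapses_runs_and_trims(self):
        assert split_fields("  a \t b\t\tc ", FLEXIBLE) == ["a", "b", "c"]
        assert split_fields("   ", FLEXIBLE) == []


class TestValidateLine:
    def line(self, *fields):
        return list(fields)

    def test_valid_bed3(self):
        assert validate_line(["chr1", "250000", "250100"], BED3) == []

    def test_score_above_range(self):
        issues = validate_line(["chr1", "0", "10", "a", "1001"], BED5)
        assert codes(issues) == [Code.SCORE_RANGE]

    def test_negative_start(self):
        issues = validate_line(["chr1", "-1", "10"], BED3)
        assert codes(issues) == [Code.NEGATIVE_COORD]

    def test_strand_dot_accepted(self):
        assert validate_line(["chr1", "0", "10", "a", "0", "."], BedVariant(6)) == []

    def test_bad_strand(self):
        issues = validate_line(["chr1", "0", "10", "a", "0", "x"], BedVariant(6))
        assert codes(issues) == [Code.STRAND_SYMBOL]

    def test_thick_start_below_chrom_start(self):
        issues = validate_line(
            ["chr1", "100", "200", "a", "0", "+", "50"], BedVariant(7)
        )
        assert codes(issues) == [Code.THICK_BOUNDS]

    def test_thick_chain_valid(self):
        assert (
            validate_line(
                ["chr1", "100", "200", "a", "0", "+", "120", "180"], BedVariant(8)
            )
            == []
        )

    def test_block_list_longer_than_count(self):
        issues = validate_line(
            ["chr1", "0", "300", "a", "0", "+", "0", "300", "0",
             "2", "100,100,100", "0,200"],
            BedVariant(12),
        )
        assert Code.BLOCK_LIST_LENGTH in codes(issues)

    def test_trailing_comma_tolerated(self):
        assert (
            validate_line(
                ["chr1", "0", "300", "a", "0", "+", "0", "300", "0",
                 "2", "100,100,", "0,200,"],
                BedVariant(12),
            )
            == []
        )

    def test_rgb_rules(self):
        base = ["chr1", "0", "10", "a", "0", "+", "0", "10"]
        assert validate_line(base + ["0"], BedVariant(9)) == []
        assert validate_line(base + ["1,2,3"], BedVariant(9)) == []
        assert codes(validate_line(base + ["256,0,0"], BedVariant(9))) == [Code.RGB_RANGE]
        assert codes(validate_line(base + ["1,2"], BedVariant(9))) == [Code.RGB_FORMAT]

    def test_dot_name_is_an_ordinary_name(self):
        assert validate_line(["chr1", "0", "10", "."], BedVariant(4)) == []

    def test_empty_field_reported_once(self):
        issues = validate_line(["chr1", "", "10"], BED3)
        assert codes(issues) == [Code.MISSING_FIELD]

    def test_chrom_charset(self):
        assert codes(validate_line(["chr@1", "0", "10"], BED3)) == [Code.CHROM_NAME]
        assert validate_line(["GL000008.2", "0", "10"], BED3) == []
        assert codes(validate_line(["N" * 256, "0", "10"], BED3)) == [Code.CHROM_NAME]

    def test_zero_length_interval_accepted(self):
        assert validate_line(["chr1", "250000", "250000"], BED3) == []

    def test_score_sweep_matches_brute_force_oracle(self):
        # Exhaustive: a BED5 line is valid iff 0 <= score <= 1000.
        for score in range(-5, 1006):
            issues = validate_line(
                ["chr1", "250000", "250100", "a", str(score)], BED5
            )
            assert (issues == []) == (0 <= score <= 1000), score

    @pytest.mark.parametrize(
        "n,fields",
        [
            (5, ["chr1", "0", "10", "a", "2000"]),
            (6, ["chr1", "-4", "10", "a", "0", "+"]),
        ],
    )
    def test_monotone_rule_inheritance(self, n, fields):
        # A line failing a rule at BEDn keeps failing at every higher
        # variant that includes the offending field.
        filler = {6: "+", 7: "0", 8: "10", 9: "0", 10: "1", 11: "10", 12: "0"}
        assert validate_line(fields, BedVariant(n)) != []
        for m in range(n + 1, 13):
            fields = fields + [filler[m]]
            if m in (10, 11):
                continue
            assert validate_line(fields, BedVariant(m)) != [], m


class TestValidateFile:
    def write(self, tmp_path, content, name="t.bed"):
        path = tmp_path / name
        path.write_text(content, newline="")
        return path

    def test_space_delimited_file_valid_in_flexible(self, tmp_path):
        path = self.write(tmp_path, "chr1 250000 250100\nchr2 250100 250300\n")
        assert validate_file(path, FLEXIBLE).valid

    def test_blank_lines_permitted(self, tmp_path):
        path = self.write(tmp_path, "chr1\t250000\t250100\n\nchr2\t250100\t250300\n")
        report = validate_file(path, FLEXIBLE)
        assert report.valid
        assert report.blank_line_count == 1
        assert report.record_count == 2

    def test_empty_file_valid(self, tmp_path):
        report = validate_file(self.write(tmp_path, ""))
        assert report.valid
        assert report.record_count == 0

    def test_ten_field_file_prohibited(self, tmp_path):
        line = "\t".join(
            ["chr1", "250000", "250500", "a", "500", "+", "250000", "250500", "0", "1"]
        )
        report = validate_file(self.write(tmp_path, line + "\n"))
        assert not report.valid
        assert [i.code for i in report.errors] == [Code.PROHIBITED_VARIANT]

    def test_mixed_field_count(self, tmp_path):
        content = "chr1\t250000\t250100\nchr1\t250200\t250300\tname\n"
        report = validate_file(self.write(tmp_path, content))
        assert [i.code for i in report.errors] == [Code.MIXED_FIELD_COUNT]

    def test_custom_mode_skips_custom_fields(self, tmp_path):
        # 5 fields, 3 declared standard: trailing junk is custom data.
        path = self.write(tmp_path, "chr1\t250000\t250100\tfoo\tnot-a-score\n")
        assert validate_file(path, mode="custom", declared_variant=BedVariant(3)).valid
        assert not validate_file(path).valid  # strict BED5 reads field 5 as score

    def test_comment_lines_skipped_only_on_request(self, tmp_path):
        path = self.write(tmp_path, "#comment\nchr1\t250000\t250100\n")
        strict = validate_file(path)
        assert not strict.valid
        lenient = validate_file(path, Dialect(skip_comment_lines=True))
        assert lenient.valid
        assert lenient.comment_line_count == 1

    def test_crlf_is_warning_not_error(self, tmp_path):
        path = self.write(tmp_path, "chr1\t250000\t250100\r\n")
        report = validate_file(path)
        assert report.valid
        assert any(i.code == Code.CRLF_LINE_ENDING for i in report.issues)

    def test_undecodable_bytes_flagged(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_bytes(b"chr1\t250000\t250100\n\xff\xfe\t1\t2\n")
        report = validate_file(path)
        assert any(i.code == Code.ENCODING for i in report.errors)

    def test_verdict_is_deterministic(self, tmp_path):
        path = self.write(tmp_path, "chr1\t250000\t250100\tx\t1001\n")
        first = validate_file(path).to_dict()
        assert validate_file(path).to_dict() == first


class TestCli:
    def run(self, *args):
        return subprocess.run(
            [sys.executable, "-m", "bedcert", "validate", *args],
            capture_output=True,
            text=True,
        )

    def test_exit_zero_on_valid(self, tmp_path):
        path = tmp_path / "ok.bed"
        path.write_text("chr1\t250000\t250100\n")
        proc = self.run(str(path))
        assert proc.returncode == 0
        assert proc.stderr == ""

    def test_exit_one_and_coded_issue_on_invalid(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t-1\t250100\n")
        proc = self.run(str(path))
        assert proc.returncode == 1
        assert "NEGATIVE_COORD" in proc.stderr

    def test_exit_two_on_missing_file(self, tmp_path):
        proc = self.run(str(tmp_path / "absent.bed"))
        assert proc.returncode == 2
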