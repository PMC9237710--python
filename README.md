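# bedcert

A conformance suite for the BED (Browser Extensible Data) genomic-interval
format:

* **strict validator** — parses BED3–BED12 against the formal format rules
  and reports coded, line-addressed errors and warnings;
* **corpus generator** — deterministically emits a 92-case expected-pass /
  expected-fail test corpus across BED3–BED12 (BED10 and BED11 are
  prohibited as standard variants, so every case there is expected-fail),
  plus minimal FASTA / chrom-sizes fixtures for secondary-input tools;
* **conformance harness** — runs external command-line tools over the
  corpus from a YAML configuration, classifies each run from its exit
  status and output streams, and scores the fraction of cases that behaved
  as expected per variant;
* **grammar fuzzer** — samples concrete BED grammars from a meta-grammar
  (tabs vs. tabs+spaces, blank/comment lines, per-field value ranges) and
  drives differential testing between two consumers;
* **badges and reports** — per-variant percentage summaries and SVG badges.

## CLI

```sh
# Validate one file; exit 0 iff it conforms.  Issues go to stderr as
# LINE:FIELD:CODE: message.
bedcert validate intervals.bed [--dialect tabs|flexible] [--custom N] [--json]

# Write the 92-case corpus (plus fixtures) and its manifest.tsv.
bedcert corpus corpus/

# Run every configured tool over the corpus and write a results table.
bedcert run --config conf.yaml --corpus corpus/ --out results.tsv

# Differential fuzzing between two configured tools.
bedcert fuzz --tool-a mytool --tool-b othertool --config conf.yaml \
             --trials 200 --seed 1 --out fuzz-report/

# Render SVG badges and a summary table from a results table.
bedcert badge --results results.tsv --out badges/
```

The harness configuration has three sections; in each invocation the
literal `FILE` is replaced with the path of the test BED file, and names
from `settings` are substituted into templates for tools that take
auxiliary inputs:

```yaml
settings:
  GENOME: corpus/mock_assembly.chrom.sizes
tools:
  mytool: mytool --in FILE
  othertool: othertool annotate --genome GENOME --bed FILE
conda-environment:
  mytool: mytool-env
```

A run classifies as *pass* only on a zero exit status with no
error/warning pattern (by default the case-insensitive substrings
`error`, `warning`, `exception`, `traceback`; overridable per tool in an
optional `patterns` section) in stdout or stderr — a warning counts as a
failure. Patterns are matched as substrings, not whole lines.

## Notes

* Coordinates are 0-based half-open; zero-length intervals
  (`chromStart == chromEnd`) are accepted.
* The default dialect is `flexible`: spaces may delimit fields when no
  field itself contains a space, and blank lines are permitted. Use
  `--dialect tabs` for tab-only splitting (where empty fields between
  consecutive tabs are rejected).
* The per-variant breakdown of the 92 corpus cases is recorded in the
  generated `manifest.tsv`; every validator rule code is exercised by at
  least one expected-fail case.
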