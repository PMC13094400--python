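# hladx — HLA genotyping data-exchange toolkit

HLA typing results move daily between typing laboratories, transplant
centers and stem-cell donor registries, and a mismatched or misread result
can mean a mismatched transplant. `hladx` implements the data standards
that make that exchange machine-checkable, for laboratory informaticians
and LIMS integrators:

- **WHO allele nomenclature** — parse and canonicalize allele names such as
  `HLA-A*01:01:01:01` (gene, 1–4 numeric fields encoding resolution,
  expression and G/P group suffixes), validate them against a versioned
  allele catalog, and map IPD-IMGT/HLA release versions to repository
  branches (3.57.0 ↔ `3570`).
- **GL Strings** — the delimiter grammar that encodes every layer of
  genotyping ambiguity in one line: `/` allele ambiguity, `~` phase, `+`
  gene copies, `|` genotype alternatives, `^` locus blocks. Parse,
  serialize, and expand to unambiguous genotypes; wrap with a GL String
  Code (`hla#3.57.0#...`) to pin the reference context.
- **Multiple allele codes (MACs)** — expand NMDP letter codes
  (`HLA-A*01:AB` → `HLA-A*01:01/HLA-A*01:02`) against a pluggable table.
- **GRID identifiers** — validate and generate the 19-character
  checksummed Global Registration Identifier for Donors; the default
  ISO 7064 mod 37,2 scheme detects 100% of single-character substitutions,
  and the fixed length catches any truncation.
- **Minimal HML** — read, write and losslessly convert (XML ↔ JSON) the
  stripped-down message profile carrying patient/center identifiers, the
  database version and a GL String per typing.
- **Tiered compliance** — validate messages against a configurable
  Minimal / General / Optional rule catalog and emit auditable JSON
  reports with per-rule evidence and corrective actions.

## Worked example

```sh
python examples/hml_validation.py
```

```
message NUTTT-IHW9224-001 from center NUTTT
patient IHW9224: typing center NUTTT, transplant center NLUT1
  HLA vs IPD-IMGT/HLA 3.57.0: HLA-A*01:01:01:01+HLA-A*02:01:01:01
  HLA vs IPD-IMGT/HLA 3.57.0: HLA-B*07:02:01:01+HLA-B*08:01:01:01
  HLA vs IPD-IMGT/HLA 3.57.0: HLA-DRB1*14:01:01/HLA-DRB1*14:54:01+HLA-DRB1*15:01:01:01

JSON serialization is 1620 bytes (lossless mirror)
minimal  tier: pass
general  tier: fail (failing: ['G1'])
```

The message reports reference cell line IHW9224 typed against release
3.57.0. The DRB1 line carries a real ambiguity — `DRB1*14:01` and
`DRB1*14:54` are identical across the antigen recognition domain, so a
typing confined to exon 2 cannot tell them apart and the GL String says so
explicitly. The message satisfies every Minimal-tier requirement (patient
and center identifiers, database version, parseable GL Strings in official
nomenclature); it fails General tier on rule G1 because it deliberately
carries no machine-readable typing method.

The other examples (`examples/*.py`) each exercise one capability:
allele-name parsing and catalog lookup, GL String expansion, GRID
generation and error detection, and MAC expansion.

There is also a CLI for shell scripting and LIMS glue — exit codes are a
stable contract (0 valid, 1 validation failure, 2 usage error):

```sh
hladx validate --tier minimal message.xml
hladx hml convert message.xml --to json -o message.json
hladx grid check 999010433218196001L
hladx glstring expand 'HLA-DRB1*14:01/HLA-DRB1*14:54+HLA-DRB1*15:01'
```

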