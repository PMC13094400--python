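# Methods

This note documents the models, conventions and deliberate design choices
behind `hladx`, in the order a validating laboratory would meet them.

## Allele nomenclature

An allele name is `prefix-gene*f1:f2:f3:f4` with 1–4 numeric fields plus an
optional suffix: one expression letter (N null, L low, S secreted, C
cytoplasmic, A aberrant, Q questionable) or one group letter (G — identical
DNA across the antigen recognition domain, P — identical protein). Fields
are labels, not numbers: leading zeros are preserved and all comparison is
string-based on the canonical serialization, which round-trips exactly.

Parsing policy:

- Names missing the `HLA-` prefix are accepted with a warning and
  normalized; wild GL Strings vary, but the canonical form must be single.
- "Little-g" group designations are rejected by the strict parser: they are
  laboratory interpretations, not official nomenclature, and are not
  consistently defined. A lenient mode flags rather than rejects them so
  the compliance engine can report them (rule M5) without crashing on them.
- G/P groups are parsed and carried but never expanded to member alleles —
  group-definition files are outside the toolkit's scope.
- A multiple-allele code is admitted only in the final field position and
  only in lenient mode; strict parsing rejects it.

Catalog validation is exact canonical-string lookup, never fuzzy. A query
typed *finer* than any catalog entry of the same lineage returns a distinct
"unknown at this resolution" outcome, because "the release does not name
this 4-field variant" and "this allele does not exist" require different
corrective actions. Only fully numeric names are catalog-validated;
MAC-bearing names must be expanded first (the MAC module owns that step).

### Release ↔ branch mapping

Database releases are mirrored as repository branches whose names
concatenate the digits of `major.minor.patch` (3.57.0 → `3570`). The
inverse uses the width convention: last digit = patch, preceding one digit
(3-digit branch) or two digits (4-digit branch) = minor, remainder = major.
Branches outside 3–4 digits are ambiguous under this convention and are
rejected; this covers majors 1–9, minors 0–99 and patches 0–9, which spans
the actual release numbering. The round trip
`branch_to_version(version_to_branch(v)) == v` is verified exhaustively for
majors 1–5.

## GL String grammar

Five delimiters, loosest to tightest binding: `^` multilocus join, `|`
genotype alternatives, `+` haplotype/copy join, `~` phase join, `/` allele
ambiguity. The parser is a nested splitter equivalent to recursive descent
at fixed precedence; parse errors carry the character offset of the
offending segment. No level may be empty. Serialization is the exact
inverse and preserves author ordering everywhere — alternatives are never
sorted on the wire.

Genotype expansion is the Cartesian product of all allele-list and
genotype-alternative ambiguity at one locus, deduplicated under
unordered-genotype normalization (haplotype strings sorted
lexicographically, only during enumeration and comparison). Expansions
beyond a configurable cap (default 10,000) raise an explicit overflow
error; silent truncation of an ambiguity list would misreport a typing.

Whitespace is illegal in strict mode; a lenient mode strips it with a
warning. A GL String may mix resolutions within one allele list — the
parser permits it and leaves judgement to validation rules.

One deliberate scope restriction: a locus block whose leaves mix gene
symbols is treated as a consistency error by `loci_of` and rule G2. Phased
multi-gene haplotype strings (e.g. a B~C haplotype inside one block)
therefore fall outside this toolkit's consistency contract; the synthetic
generator phases within a single locus so that generated corpora satisfy
it.

GL String Codes are `namespace#version#glstring`; `#` cannot occur inside a
GL String, so the arity check is unambiguous. Cross-release translation of
allele names is refused, not attempted: a GL String is only meaningful
against the release that defined its names.

## Multiple allele codes

Generic codes substitute the final field; allele-specific codes replace the
last two fields with stored `first:second` pairs. When an allele-specific
expansion disagrees with the typed first field, the code wins and a warning
is emitted — silent override would hide a clerical error, hard failure
would reject a documented registry convention. Expansion output is always
fully numeric: expanding then testing for MACs is always false, and
expanded output parses strictly with no warnings.

## GRID identifiers

Structure is configuration, not literals: 4-character issuer + 14-character
registrant + 1 check character, 19 total. The registrant alphabet defaults
to digits; whether real-world registrant bodies are numeric or alphanumeric
is genuinely unsettled, so both are supported and the default is declared
in `GridConfig` rather than silently assumed.

The checksum is a pluggable strategy. The default is the pure ISO 7064
mod 37,2 recursive system (`P = (P + value) * 2 mod 37`, check value
`(38 − P) mod 37`, check alphabet `0-9A-Z*`); a pure-numeric mod 11,2
variant (check alphabet `0-9X`) is included. Pure systems at radix 2
detect every single-character substitution — the per-position contribution
is `δ·2^k mod M` with 2 invertible and `|δ| < M` — and every truncation is
caught by the length rule alone. Both claims are verified exhaustively in
the test suite (all 18 positions × all substitute characters × 1,000
generated identifiers; all 19 single deletions each).

Validation reports typed result kinds (wrong length, illegal character,
checksum mismatch), never exceptions: callers are validators and need the
distinction for their reports.

## Minimal HML profile

The message model keeps exactly what a receiver needs: header (message id,
creation timestamp, reporting center), samples with identifier properties
(`lab-ref` typing center, `tc-ref` transplant center, `patient-ref`), and
per-gene-family allele assignments binding a GL String to `allele-db` +
`allele-version` + date. Optional per-typing blocks: a machine-readable
typing method (description, platform, exons targeted, software + version)
and an opaque consensus-sequence payload, exportable as FASTA.

Serialization choices:

- Documents are accepted with or without an XML namespace and emitted
  without one.
- Typographic hyphens and quotes (typesetting artifacts in published
  renditions of example messages) are normalized to ASCII on read.
- Output is deterministic: fixed element order, properties sorted by key,
  byte-stable across runs. Dates are timezone-free ISO-8601.
- Unknown elements are preserved in per-container extras bags as
  canonicalized XML fragments and re-emitted verbatim, making the
  XML → model → JSON → model → XML round trip lossless on richer documents.
- The JSON serialization mirrors the model one-to-one (schema published at
  `src/hladx/data/hml.schema.json`); structure and semantics do not change
  with the container syntax. JSON output uses sorted keys and is
  byte-stable. Structural validation of incoming JSON collects *all*
  missing required paths into one error.
- The model itself is deliberately permissive (it will hold an unparseable
  GL String or version): messages must be representable in order to be
  validated, so invariant enforcement lives in the compliance rules and in
  serialization-time refusals (no samples, empty message id).

## Compliance engine

Rules live in a versioned YAML catalog (`src/hladx/data/rules.yaml`), not
in code: tier and severity assignments for contested rules are
configuration. Defaults:

| rule | tier | severity | check |
|------|------|----------|-------|
| M1 | Minimal | error | patient-ref present on every sample |
| M2 | Minimal | error | lab-ref and tc-ref present |
| M3 | Minimal | error | allele-db named, allele-version parses |
| M4 | Minimal | error | GL String present and grammar-valid |
| M5 | Minimal | error | official nomenclature only (no little-g) |
| G1 | General | error | machine-readable typing method present |
| G2 | General | error | gene family consistent with GL String loci |
| G3 | General | error | official alleles found in the declared catalog |
| O1 | Optional | error | consensus sequence accompanies each typing |
| O2 | Optional | warning | payload free of multiple allele codes |

Rule independence is engineered deliberately: M4 judges grammar with the
lenient leaf parser, M5 judges nomenclature officialdom only on strings
that parsed, G3 skips non-official leaves (they are M5's or O2's finding),
and O2 reports MAC presence. This makes each defect flip exactly one rule —
verified by mutation tests — and keeps audit reports attributable. O2
defaults to warning because registry practice tolerates MACs for ambiguity
reporting while interoperable exchange discourages them; sites that forbid
them re-map the severity in the catalog. Whether a method-less message can
satisfy the General tier is likewise a catalog decision (default: G1 is an
error), not hard-coded.

Verdict semantics: tier T passes iff every error-severity rule of tier ≤ T
passes; warnings and not-evaluated outcomes never pass silently — they
appear in the report with evidence. Tiers nest, so Optional-pass ⇒
General-pass ⇒ Minimal-pass by construction; the property is still tested
over a 1,000-message corpus. All failures are reported (no fail-fast), and
each report records the toolkit and rule-catalog versions plus a timestamp,
so re-running on recorded inputs reproduces the verdicts. "Outlier
detection" in the validation-documentation sense is realized as the bounded
checks above (version parseability, grammar caps, consistency checks);
statistical outlier detection over typing distributions is out of scope.

Retention profiles are a small constants table; the built-in HIPAA profile
is 6 years (compliance documentation must be kept at least six years from
creation or last effect). HML versions from 1.0 upward are treated as
implementing the minimum-information reporting guidelines.

## Synthetic generators

The generators emulate the *structure* of exchanged messages so that every
stage is testable offline; they do not emulate population genetics. Allele
leaves are drawn uniformly (no allele frequencies, no linkage) from the
bundled toy catalog — a 21-entry stand-in for a full release export, with
release 3.57.0, the `HLA-A*01:01:01:01`/`HLA00001` identifier pair and the
ARD-identical DRB1\*14:01/14:54 pair annotated in metadata — so catalog
membership (G3) passes by construction unless the unknown-allele defect is
requested. Passing tests therefore demonstrate contract correctness
(grammar, round trips, rule logic), not performance on realistic allele
distributions.

Default ambiguity profile: three loci (A, B, DRB1), allele lists up to 3,
up to 2 genotype alternatives, phase depth up to 2 (phase drawn with
probability 0.4) — enough to cover every delimiter across a small corpus
while keeping expansions far below the cap. All randomness flows from one
named seed, recorded in generated messages as a `generator-seed` sample
property; generation is byte-for-byte reproducible. Defect injection
mutates one targeted element per rule id (drop a property, corrupt the
version string, break the grammar, introduce a little-g form, an unknown
allele, or a MAC) and is verified to flip exactly that rule.

The golden example message is transcribed: reference cell line IHW9224,
typing center NUTTT, transplant center NLUT1, database IPD-IMGT/HLA
3.57.0, date 2024-11-20, and no typing method (the typing was extracted
from the database, not re-run). Its GL Strings are drawn from the toy
catalog, including the DRB1 ambiguity pair. It is bundled both as built
XML/JSON files and as a programmatic constructor, and the two are asserted
identical.

## Problem sizes and numerical choices

Test-suite sweep sizes are the published contract sizes: 5,000 versions for
the branch round trip, 1,000 GRIDs × exhaustive deletion/substitution,
1,000 seeded GL Strings against the brute-force expansion oracle, 1,000
synthetic messages for tier monotonicity. The whole suite runs in well
under a minute on one CPU.

Known limitations: no G/P group membership expansion, no serologic antigen
mapping, no cross-release allele translation, no sequence-level ambiguity
resolution (ARD identity is carried as catalog metadata only), branch
mapping limited to single-digit majors, and the consistency contract
excludes phased multi-gene haplotypes as noted above.
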