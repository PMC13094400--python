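# Tiered validation-rule catalog for minimal-HML messages.
#
# Tiers nest: General expands on Minimal, Optional expands on General.  The
# tier verdict for T passes iff every error-severity rule of tier <= T
# passes.  Severities for contested rules (MAC presence, method-less
# messages) are deliberately configuration, not code: re-map them here
# without touching the toolkit.
catalog_version: "1.0.0"
rules:
  - id: M1
    tier: minimal
    severity: error
    description: Every sample carries a patient identifier (patient-ref property).
    corrective_action: Add <property name="patient-ref" value="..."/> to each sample.
  - id: M2
    tier: minimal
    severity: error
    description: Every sample carries center identifiers (lab-ref and tc-ref properties).
    corrective_action: Add lab-ref (typing center) and tc-ref (transplant center) properties.
  - id: M3
    tier: minimal
    severity: error
    description: Every allele assignment names its database and a parseable release version.
    corrective_action: Set allele-db and allele-version (major.minor.patch) on each allele-assignment.
  - id: M4
    tier: minimal
    severity: error
    description: Every allele assignment carries a GL String that parses under the ambiguity grammar.
    corrective_action: Supply a well-formed GL String in the <glstring> element.
  - id: M5
    tier: minimal
    severity: error
    description: Only official WHO nomenclature allele names are used (no little-g groupings).
    corrective_action: Replace unofficial group designations with official allele names or G/P groups.
  - id: G1
    tier: general
    severity: error
    description: A machine-readable typing method with a nonempty description is present.
    corrective_action: Add a <typing-method> block with at least a description.
  - id: G2
    tier: general
    severity: error
    description: The gene family of each typing is consistent with the loci named in its GL String.
    corrective_action: Align the typing gene-family attribute with the GL String locus prefixes.
  - id: G3
    tier: general
    severity: error
    description: Every fully resolved allele name is present in the declared catalog release.
    corrective_action: Re-call against the declared release or correct the allele names.
  - id: O1
    tier: optional
    severity: error
    description: A consensus-sequence payload accompanies each typing.
    corrective_action: Attach the consensus sequence supporting the allele assignment.
  - id: O2
    tier: optional
    severity: warning
    description: The GL String payload is free of multiple-allele codes.
    corrective_action: Expand MACs to fully enumerated allele lists before exchange.
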