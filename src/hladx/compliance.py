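"""Tiered compliance validation of minimal-HML messages.

Recommendations for typing-data exchange come in three nested tiers —
Minimal (the elements without which a message cannot be interpreted:
patient and center identifiers, database version, a GL String in official
nomenclature), General (context that makes the result reproducible: a
machine-readable typing method, locus consistency, catalog membership) and
Optional (raw-data accompaniment and fully enumerated, MAC-free payloads).
A message passing a higher tier necessarily passes every lower one.

Rules live in a versioned data catalog (YAML), not in code constants, so
implementers can re-map tiers and severities without touching the toolkit.
Every evaluated rule appears in the report — multiple failures are all
reported, never fail-fast — and reports are self-describing: they record
the toolkit and rule-catalog versions that produced them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Optional

import yaml

from . import __version__
from .glstring import GlParseError, iter_leaves, loci_of, parse_glstring
from .hml import HmlMessage
from .mac import MacTable, contains_mac
from .nomenclature import (
    AlleleCatalog,
    NomenclatureError,
    ReleaseVersion,
    validate_against_catalog,
)

__all__ = [
    "ValidationRule",
    "RuleOutcome",
    "ComplianceReport",
    "ComplianceError",
    "RetentionProfile",
    "TIERS",
    "load_rule_catalog",
    "run_compliance",
    "report_to_json",
    "retention_minimum",
    "miring_capable",
    "RETENTION_PROFILES",
]

TIERS = ("minimal", "general", "optional")
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not_evaluated"


class ComplianceError(ValueError):
    pass


@dataclass(frozen=True)
class ValidationRule:
    rule_id: str
    tier: str
    severity: str
    description: str
    corrective_action: str

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ComplianceError(f"rule {self.rule_id}: unknown tier {self.tier!r}")
        if self.severity not in ("error", "warning", "info"):
            raise ComplianceError(
                f"rule {self.rule_id}: unknown severity {self.severity!r}"
            )
        if self.tier == "minimal" and self.severity != "error":
            raise ComplianceError(
                f"rule {self.rule_id}: minimal-tier rules must have severity error"
            )


@dataclass
class RuleOutcome:
    rule_id: str
    tier: str
    severity: str
    status: str  # pass | fail | not_evaluated
    evidence: str
    corrective_action: str


@dataclass
class ComplianceReport:
    message_ref: str
    tier: str
    outcomes: list[RuleOutcome]
    verdicts: dict[str, bool]
    timestamp: str
    toolkit_version: str
    catalog_version: str

    @property
    def verdict(self) -> bool:
        return self.verdicts[self.tier]


@dataclass(frozen=True)
class RetentionProfile:
    name: str
    minimum_years: int

    def __post_init__(self) -> None:
        if self.minimum_years <= 0:
            raise ComplianceError("retention period must be positive")


#: Built-in retention profiles for compliance documentation.  The HIPAA
#: Privacy Rule requires covered entities to keep compliance documentation
#: for at least six years from creation or last effect.
RETENTION_PROFILES: dict[str, RetentionProfile] = {
    "HIPAA": RetentionProfile("HIPAA", 6),
}

_DEFAULT_CATALOG_PATH = Path(__file__).parent / "data" / "rules.yaml"


def load_rule_catalog(path: str | Path = _DEFAULT_CATALOG_PATH) -> tuple[str, list[ValidationRule]]:
    """Load the rule catalog; returns (catalog_version, rules)."""
    doc = yaml.safe_load(Path(path).read_text())
    rules = [
        ValidationRule(
            rule_id=r["id"],
            tier=r["tier"],
            severity=r["severity"],
            description=r["description"],
            corrective_action=r["corrective_action"],
        )
        for r in doc["rules"]
    ]
    ids = [r.rule_id for r in rules]
    if len(set(ids)) != len(ids):
        raise ComplianceError("duplicate rule ids in catalog")
    return str(doc["catalog_version"]), rules


# ---------------------------------------------------------------------------
# Rule predicates.  Each returns (status, evidence).  The lenient GL parse
# (MACs and unofficial forms admitted) separates grammar validity (M4) from
# nomenclature officialdom (M5) and MAC presence (O2).


def _each_typing(msg: HmlMessage):
    for s in msg.samples:
        for i, t in enumerate(s.typings):
            yield s, i, t


def _check_m1(msg, ctx):
    bad = [s.sample_id for s in msg.samples if not s.properties.get("patient-ref")]
    if bad:
        return FAIL, "missing patient-ref at " + ", ".join(
            f"sample[{b}]/property[patient-ref]" for b in bad
        )
    return PASS, "patient-ref present on every sample"


def _check_m2(msg, ctx):
    bad = []
    for s in msg.samples:
        for key in ("lab-ref", "tc-ref"):
            if not s.properties.get(key):
                bad.append(f"sample[{s.sample_id}]/property[{key}]")
    if bad:
        return FAIL, "missing center identifiers at " + ", ".join(bad)
    return PASS, "lab-ref and tc-ref present on every sample"


def _check_m3(msg, ctx):
    bad = []
    for s, i, t in _each_typing(msg):
        path = f"sample[{s.sample_id}]/typing[{i}]/allele-assignment"
        if not t.assignment.allele_db:
            bad.append(f"{path}@allele-db")
        try:
            ReleaseVersion.parse(t.assignment.allele_version)
        except NomenclatureError:
            bad.append(f"{path}@allele-version={t.assignment.allele_version!r}")
    if bad:
        return FAIL, "database/version defects at " + ", ".join(bad)
    return PASS, "allele-db and parseable allele-version on every assignment"


def _lenient_parse(glstring: str):
    return parse_glstring(glstring, allow_mac=True, allow_unofficial=True)


def _check_m4(msg, ctx):
    bad = []
    for s, i, t in _each_typing(msg):
        path = f"sample[{s.sample_id}]/typing[{i}]/glstring"
        if not t.assignment.glstring:
            bad.append(f"{path} (empty)")
            continue
        try:
            _lenient_parse(t.assignment.glstring)
        except GlParseError as exc:
            bad.append(f"{path}: {exc}")
    if bad:
        return FAIL, "GL String defects at " + "; ".join(bad)
    return PASS, "every GL String parses under the ambiguity grammar"


def _check_m5(msg, ctx):
    bad = []
    parsed_any = False
    for s, i, t in _each_typing(msg):
        try:
            ast = _lenient_parse(t.assignment.glstring)
        except GlParseError:
            continue  # grammar failures belong to M4
        parsed_any = True
        for leaf in iter_leaves(ast):
            if leaf.unofficial_group:
                bad.append(
                    f"sample[{s.sample_id}]/typing[{i}]: unofficial little-g form {leaf}"
                )
    if not parsed_any:
        return NOT_EVALUATED, "no grammatically valid GL String to inspect"
    if bad:
        return FAIL, "; ".join(bad)
    return PASS, "all leaves use official WHO nomenclature"


def _check_g1(msg, ctx):
    bad = [
        f"sample[{s.sample_id}]/typing[{i}]"
        for s, i, t in _each_typing(msg)
        if t.method is None or not t.method.description
    ]
    if bad:
        return FAIL, "no machine-readable typing method at " + ", ".join(bad)
    return PASS, "typing method with description present on every typing"


def _check_g2(msg, ctx):
    bad = []
    for s, i, t in _each_typing(msg):
        try:
            ast = _lenient_parse(t.assignment.glstring)
        except GlParseError:
            continue
        loci = loci_of(ast, strict=False)
        path = f"sample[{s.sample_id}]/typing[{i}]"
        if None in loci:
            bad.append(f"{path}: locus block mixes gene symbols")
        prefixes = {leaf.prefix for leaf in iter_leaves(ast)}
        if t.gene_family and prefixes and prefixes != {t.gene_family}:
            bad.append(
                f"{path}: gene-family {t.gene_family!r} vs GL String namespace "
                f"{sorted(prefixes)}"
            )
    if bad:
        return FAIL, "; ".join(bad)
    return PASS, "gene families consistent with GL String loci"


def _check_g3(msg, ctx):
    catalog: Optional[AlleleCatalog] = ctx.get("catalog")
    if catalog is None:
        return NOT_EVALUATED, "no allele catalog supplied"
    bad = []
    for s, i, t in _each_typing(msg):
        try:
            ast = _lenient_parse(t.assignment.glstring)
        except GlParseError:
            continue
        for leaf in iter_leaves(ast):
            if not leaf.is_official:
                continue  # MAC / unofficial leaves are judged by O2 and M5
            if not validate_against_catalog(leaf, catalog):
                bad.append(
                    f"sample[{s.sample_id}]/typing[{i}]: {leaf} not in release "
                    f"{catalog.release}"
                )
    if bad:
        return FAIL, "; ".join(bad)
    return PASS, f"all alleles found in catalog release {catalog.release}"


def _check_o1(msg, ctx):
    bad = [
        f"sample[{s.sample_id}]/typing[{i}]"
        for s, i, t in _each_typing(msg)
        if not t.consensus
    ]
    if bad:
        return FAIL, "no consensus sequence at " + ", ".join(bad)
    return PASS, "consensus sequence present on every typing"


def _check_o2(msg, ctx):
    bad = [
        f"sample[{s.sample_id}]/typing[{i}]"
        for s, i, t in _each_typing(msg)
        if contains_mac(t.assignment.glstring)
    ]
    if bad:
        return FAIL, "multiple-allele codes at " + ", ".join(bad)
    return PASS, "payloads are MAC-free"


_CHECKS: dict[str, Callable] = {
    "M1": _check_m1,
    "M2": _check_m2,
    "M3": _check_m3,
    "M4": _check_m4,
    "M5": _check_m5,
    "G1": _check_g1,
    "G2": _check_g2,
    "G3": _check_g3,
    "O1": _check_o1,
    "O2": _check_o2,
}


def run_compliance(
    msg: HmlMessage,
    tier: str,
    catalog: Optional[AlleleCatalog] = None,
    mac_table: Optional[MacTable] = None,
    rule_catalog_path: str | Path = _DEFAULT_CATALOG_PATH,
) -> ComplianceReport:
    """Evaluate every rule of tier <= *tier* against *msg*.

    All failures are reported (no fail-fast).  A rule whose inputs are
    unavailable (e.g. catalog membership with no catalog) is reported as
    not-evaluated, never as a silent pass.  The per-tier verdict passes iff
    every error-severity rule of that tier or below passes.
    """
    if tier not in TIERS:
        raise ComplianceError(f"unknown tier {tier!r}; expected one of {TIERS}")
    catalog_version, rules = load_rule_catalog(rule_catalog_path)
    ctx = {"catalog": catalog, "mac_table": mac_table}

    outcomes: list[RuleOutcome] = []
    for rule in rules:
        if _TIER_RANK[rule.tier] > _TIER_RANK[tier]:
            continue
        check = _CHECKS.get(rule.rule_id)
        if check is None:
            raise ComplianceError(f"rule {rule.rule_id} has no registered check")
        status, evidence = check(msg, ctx)
        outcomes.append(
            RuleOutcome(
                rule_id=rule.rule_id,
                tier=rule.tier,
                severity=rule.severity,
                status=status,
                evidence=evidence,
                corrective_action=rule.corrective_action if status == FAIL else "",
            )
        )

    verdicts = {}
    for t in TIERS:
        if _TIER_RANK[t] > _TIER_RANK[tier]:
            break
        verdicts[t] = all(
            o.status != FAIL
            for o in outcomes
            if o.severity == "error" and _TIER_RANK[o.tier] <= _TIER_RANK[t]
        )

    return ComplianceReport(
        message_ref=msg.header.message_id,
        tier=tier,
        outcomes=outcomes,
        verdicts=verdicts,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        toolkit_version=__version__,
        catalog_version=catalog_version,
    )


def report_to_json(report: ComplianceReport) -> str:
    """Stable JSON form of a report (schema published in the repo).  Two runs
    on the same input differ only in the timestamp field."""
    doc = {
        "message_ref": report.message_ref,
        "tier": report.tier,
        "verdict": "pass" if report.verdict else "fail",
        "verdicts": {t: ("pass" if v else "fail") for t, v in report.verdicts.items()},
        "outcomes": [
            {
                "rule_id": o.rule_id,
                "tier": o.tier,
                "severity": o.severity,
                "status": o.status,
                "evidence": o.evidence,
                "corrective_action": o.corrective_action,
            }
            for o in report.outcomes
        ],
        "timestamp": report.timestamp,
        "toolkit_version": report.toolkit_version,
        "catalog_version": report.catalog_version,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def retention_minimum(profile_name: str) -> int:
    """Minimum retention period in years for compliance documentation under
    the named regulatory profile."""
    profile = RETENTION_PROFILES.get(profile_name)
    if profile is None:
        raise ComplianceError(
            f"unknown retention profile {profile_name!r}; available: "
            + ", ".join(sorted(RETENTION_PROFILES))
        )
    return profile.minimum_years


def miring_capable(hml_version: str) -> bool:
    """True iff an HML version implements the minimum-information reporting
    guidelines — versions 1.0 and later do."""
    parts = hml_version.strip().split(".")
    if not parts or not all(p.isdigit() for p in parts):
        raise ComplianceError(f"malformed HML version {hml_version!r}")
    nums = tuple(int(p) for p in parts)
    return nums >= (1, 0) if len(nums) >= 2 else nums >= (1,)
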