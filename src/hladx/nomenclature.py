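"""WHO HLA allele nomenclature: names, catalogs and release versions.

An HLA allele name such as ``HLA-A*01:01:01:01`` carries a namespace prefix
(``HLA``), a gene symbol (``A``), one to four colon-separated numeric fields
(field count encodes typing resolution), an optional one-letter expression
suffix (N/L/S/C/A/Q) and an optional G/P group suffix for alleles grouped by
identity over the antigen recognition domain.  Allele names are labels, not
numbers: leading zeros are significant and comparison is string-based on the
canonical serialization.

Reference sequences live in versioned releases of the IPD-IMGT/HLA database;
each release is mirrored as a repository branch whose name concatenates the
digits of the version (branch ``3570`` for release 3.57.0).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

__all__ = [
    "AlleleName",
    "AlleleCatalog",
    "ReleaseVersion",
    "CatalogLookup",
    "LookupStatus",
    "NomenclatureError",
    "NomenclatureWarning",
    "parse_allele_name",
    "resolution_of",
    "validate_against_catalog",
    "load_catalog",
    "version_to_branch",
    "branch_to_version",
    "EXPRESSION_SUFFIXES",
    "GROUP_SUFFIXES",
]

EXPRESSION_SUFFIXES = frozenset("NLSCAQ")
GROUP_SUFFIXES = frozenset("GP")
DEFAULT_PREFIX = "HLA"

_GENE_RE = re.compile(r"[A-Z][A-Z0-9]*\Z")
_MAC_RE = re.compile(r"[A-Z]{2,}\Z")
_ACCESSION_RE = re.compile(r"HLA\d+\Z")


class NomenclatureError(ValueError):
    """A malformed allele name, version or catalog file."""


class NomenclatureWarning(UserWarning):
    """Recoverable deviations from canonical form (e.g. a missing prefix)."""


@dataclass(frozen=True)
class AlleleName:
    """Structured form of one WHO-nomenclature allele designation.

    ``fields`` holds the raw field strings verbatim ("01" is distinct from
    "1").  A name may carry at most one of ``expression_suffix`` (expression
    status, e.g. N for null) or ``group_suffix`` (G/P group).  Two flags mark
    non-official leaf forms that only the lenient parser admits: ``mac`` is a
    multiple-allele-code field in final position, ``unofficial_group`` is a
    little-g designation.
    """

    prefix: Optional[str]
    gene: str
    fields: tuple[str, ...]
    expression_suffix: Optional[str] = None
    group_suffix: Optional[str] = None
    mac: Optional[str] = None
    unofficial_group: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 4:
            raise NomenclatureError(
                f"allele name must have 1-4 fields, got {len(self.fields)}"
            )
        if self.group_suffix is not None and len(self.fields) < 2:
            raise NomenclatureError(
                "G/P group suffixes are defined at two-field resolution or finer"
            )
        if self.expression_suffix is not None and self.group_suffix is not None:
            raise NomenclatureError(
                "a name cannot carry both an expression and a group suffix"
            )

    @property
    def is_official(self) -> bool:
        """True when the name uses only official WHO nomenclature forms."""
        return self.mac is None and not self.unofficial_group

    def __str__(self) -> str:
        prefix = self.prefix or DEFAULT_PREFIX
        body = ":".join(self.fields)
        suffix = self.expression_suffix or self.group_suffix or ""
        if self.unofficial_group:
            suffix = "g"
        return f"{prefix}-{self.gene}*{body}{suffix}"


@dataclass(frozen=True)
class ReleaseVersion:
    """An IPD-IMGT/HLA database release, e.g. 3.57.0."""

    major: int
    minor: int
    patch: int

    def __post_init__(self) -> None:
        if min(self.major, self.minor, self.patch) < 0:
            raise NomenclatureError("version components must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "ReleaseVersion":
        parts = text.strip().split(".")
        if len(parts) != 3 or not all(p.isdigit() for p in parts):
            raise NomenclatureError(
                f"release version must be 'major.minor.patch', got {text!r}"
            )
        return cls(int(parts[0]), int(parts[1]), int(parts[2]))

    def __str__(self) -> str:
        return f"{self.major}.{self.minor}.{self.patch}"


class LookupStatus(Enum):
    FOUND = "found"
    NOT_FOUND = "not_found"
    UNKNOWN_AT_RESOLUTION = "unknown_at_resolution"


@dataclass(frozen=True)
class CatalogLookup:
    """Outcome of a catalog query: an accession, or a typed miss."""

    status: LookupStatus
    accession: Optional[str] = None

    def __bool__(self) -> bool:
        return self.status is LookupStatus.FOUND


@dataclass
class AlleleCatalog:
    """Allele name -> accession mapping for one database release.

    ``metadata`` may carry per-entry annotations, e.g. the name of an
    antigen-recognition-domain-identical partner allele.
    """

    release: ReleaseVersion
    entries: dict[str, str]
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, accession in self.entries.items():
            parse_allele_name(name)  # raises on malformed keys
            if not _ACCESSION_RE.match(accession):
                raise NomenclatureError(
                    f"accession {accession!r} for {name} does not match 'HLA' + digits"
                )
            if accession in seen:
                raise NomenclatureError(
                    f"accession {accession} assigned to both {seen[accession]} and {name}"
                )
            seen[accession] = name


def parse_allele_name(
    text: str,
    *,
    allow_mac: bool = False,
    allow_unofficial: bool = False,
) -> AlleleName:
    """Parse one allele name into its structured form.

    The strict default accepts only official WHO forms.  ``allow_mac`` admits
    a multiple-allele-code (uppercase letters) in the final field position;
    ``allow_unofficial`` admits little-g group designations, flagged on the
    result rather than normalized away.  Names without the "HLA-" prefix are
    accepted with a warning and normalized to prefixed form.
    """
    if not text:
        raise NomenclatureError("empty allele name")
    if text != text.strip() or any(c.isspace() for c in text):
        raise NomenclatureError(f"whitespace in allele name {text!r}")

    star = text.find("*")
    if star < 0:
        raise NomenclatureError(f"missing '*' separator in {text!r}")
    head, body = text[:star], text[star + 1 :]

    if "-" in head:
        prefix, gene = head.split("-", 1)
        if not prefix:
            raise NomenclatureError(f"empty prefix before '-' in {text!r} (position 0)")
    else:
        prefix, gene = None, head
        warnings.warn(
            f"allele name {text!r} lacks the '{DEFAULT_PREFIX}-' prefix; "
            "normalizing to prefixed canonical form",
            NomenclatureWarning,
            stacklevel=2,
        )
    if not _GENE_RE.match(gene):
        raise NomenclatureError(f"invalid gene symbol {gene!r} in {text!r}")

    raw_fields = body.split(":")
    if len(raw_fields) > 4:
        raise NomenclatureError(
            f"too many fields in {text!r}: {len(raw_fields)} > 4"
        )

    expression: Optional[str] = None
    group: Optional[str] = None
    mac: Optional[str] = None
    unofficial = False

    fields: list[str] = []
    for i, f in enumerate(raw_fields):
        pos = star + 1 + sum(len(x) + 1 for x in raw_fields[:i])
        if not f:
            raise NomenclatureError(f"empty field in {text!r} at position {pos}")
        last = i == len(raw_fields) - 1
        if f.isdigit():
            fields.append(f)
        elif last and f[:-1].isdigit() and f[:-1]:
            suffix = f[-1]
            if suffix in EXPRESSION_SUFFIXES:
                expression = suffix
            elif suffix in GROUP_SUFFIXES:
                group = suffix
            elif suffix == "g":
                if not allow_unofficial:
                    raise NomenclatureError(
                        f"little-g group designation in {text!r} at position {pos}: "
                        "unofficial groupings are not valid WHO nomenclature"
                    )
                unofficial = True
            else:
                raise NomenclatureError(
                    f"unknown suffix {suffix!r} in {text!r} at position {pos}"
                )
            fields.append(f[:-1])
        elif last and allow_mac and _MAC_RE.match(f):
            mac = f
            fields.append(f)
        else:
            kind = "multiple-allele code" if _MAC_RE.match(f) else "non-digit field"
            raise NomenclatureError(
                f"{kind} {f!r} in {text!r} at position {pos}"
            )

    return AlleleName(
        prefix=prefix or DEFAULT_PREFIX,
        gene=gene,
        fields=tuple(fields),
        expression_suffix=expression,
        group_suffix=group,
        mac=mac,
        unofficial_group=unofficial,
    )


def resolution_of(name: AlleleName) -> int:
    """Typing resolution as the number of reported fields (1-4)."""
    return len(name.fields)


def validate_against_catalog(name: AlleleName, catalog: AlleleCatalog) -> CatalogLookup:
    """Exact canonical-string lookup of *name* in *catalog*.

    No fuzzy matching is performed.  A name typed finer than any catalog entry
    of the same lineage yields UNKNOWN_AT_RESOLUTION rather than a plain miss,
    so callers can distinguish "absent" from "absent at this resolution".
    """
    key = str(name)
    accession = catalog.entries.get(key)
    if accession is not None:
        return CatalogLookup(LookupStatus.FOUND, accession)
    # Is some catalog entry a strict field-prefix of the query (query finer)?
    for entry in catalog.entries:
        cat = parse_allele_name(entry)
        if (
            cat.gene == name.gene
            and len(cat.fields) < len(name.fields)
            and cat.fields == name.fields[: len(cat.fields)]
        ):
            return CatalogLookup(LookupStatus.UNKNOWN_AT_RESOLUTION)
    return CatalogLookup(LookupStatus.NOT_FOUND)


def load_catalog(path: str | Path) -> AlleleCatalog:
    """Load an allele catalog from two-column tab-separated text.

    Lines starting with '#' are comments.  The first non-comment line holds
    the release version; each following line is ``name<TAB>accession`` with an
    optional third column of ``key=value`` pairs joined by ';'.
    """
    release: Optional[ReleaseVersion] = None
    entries: dict[str, str] = {}
    metadata: dict[str, dict[str, str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if release is None:
            release = ReleaseVersion.parse(line)
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise NomenclatureError(
                f"{path}:{lineno}: expected 'name<TAB>accession', got {raw!r}"
            )
        name = str(parse_allele_name(cols[0]))
        entries[name] = cols[1].strip()
        if len(cols) > 2 and cols[2].strip():
            meta = {}
            for pair in cols[2].split(";"):
                k, _, v = pair.partition("=")
                meta[k.strip()] = v.strip()
            metadata[name] = meta
    if release is None:
        raise NomenclatureError(f"{path}: missing release-version header line")
    return AlleleCatalog(release=release, entries=entries, metadata=metadata)


def version_to_branch(v: ReleaseVersion) -> str:
    """Repository branch name for a release: digits of major, minor, patch
    concatenated with no separators (3.57.0 -> "3570")."""
    return f"{v.major}{v.minor}{v.patch}"


def branch_to_version(branch: str) -> ReleaseVersion:
    """Inverse of :func:`version_to_branch` under the width convention:
    last digit is the patch, the preceding one (3-digit branch) or two
    (4-digit branch) digits are the minor, the remainder is the major.

    Branches outside 3-4 digits are ambiguous under this convention and are
    rejected.
    """
    if not branch.isdigit():
        raise NomenclatureError(f"branch {branch!r} is not all digits")
    if not 3 <= len(branch) <= 4:
        raise NomenclatureError(
            f"branch {branch!r} must be 3-4 digits (e.g. '3570' for 3.57.0)"
        )
    patch = int(branch[-1])
    if len(branch) == 3:
        major, minor = int(branch[0]), int(branch[1])
    else:
        major, minor = int(branch[0]), int(branch[1:3])
    return ReleaseVersion(major, minor, patch)
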