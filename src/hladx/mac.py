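"""NMDP Multiple Allele Codes (MACs): expansion and detection.

A MAC is an uppercase letter code standing in for a list of allele
possibilities in one allele name, e.g. ``HLA-A*01:AB`` where AB encodes the
final fields 01 and 02.  Codes come in two kinds: *generic* codes substitute
the final field only, *allele-specific* codes replace the last two fields
with full first:second pairs.  MACs remain in wide registry use for
ambiguity reporting, but standardized interoperable exchange should carry
fully enumerated GL Strings instead — the compliance rules therefore treat a
MAC-bearing payload as allowed-but-reportable.

The code registry itself is external; tables are pluggable two-column
tab-separated text.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

from .nomenclature import AlleleName, parse_allele_name

__all__ = [
    "MacTable",
    "MacEntry",
    "MacError",
    "UnknownMacError",
    "MacStructureError",
    "MacWarning",
    "load_mac_table",
    "expand_mac",
    "contains_mac",
]

_CODE_RE = re.compile(r"[A-Z]{2,}\Z")
_PAIR_RE = re.compile(r"\d+:\d+\Z")
# a leaf's final field that is all uppercase letters, length >= 2
_MAC_FIELD_RE = re.compile(r":([A-Z]{2,})(?=$|[\^\|\+~/])")


class MacError(ValueError):
    pass


class UnknownMacError(MacError):
    """Code absent from the supplied table."""


class MacStructureError(MacError):
    """Code in a position the MAC system does not define."""


class MacWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MacEntry:
    code: str
    allele_specific: bool
    expansions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise MacError(f"MAC code must be >=2 uppercase letters, got {self.code!r}")
        if not self.expansions:
            raise MacError(f"MAC {self.code} has an empty expansion list")
        for e in self.expansions:
            if self.allele_specific:
                if not _PAIR_RE.match(e):
                    raise MacError(
                        f"allele-specific MAC {self.code}: expansion {e!r} is not "
                        "a 'first:second' field pair"
                    )
            elif not e.isdigit():
                raise MacError(
                    f"generic MAC {self.code}: expansion {e!r} is not a numeric field"
                )


@dataclass(frozen=True)
class MacTable:
    entries: dict[str, MacEntry]


def load_mac_table(path: str | Path) -> MacTable:
    """Load a MAC table: ``code<TAB>expansion/expansion...`` per line, with a
    third ``*`` column marking allele-specific codes; '#' comments."""
    entries: dict[str, MacEntry] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise MacError(f"{path}:{lineno}: expected 'code<TAB>expansions', got {raw!r}")
        code = cols[0].strip()
        if code in entries:
            raise MacError(f"{path}:{lineno}: duplicate MAC code {code}")
        allele_specific = len(cols) > 2 and cols[2].strip() == "*"
        entries[code] = MacEntry(
            code=code,
            allele_specific=allele_specific,
            expansions=tuple(cols[1].split("/")),
        )
    return MacTable(entries=entries)


def expand_mac(name_with_code: str, table: MacTable) -> list[AlleleName]:
    """Expand one MAC-bearing allele name into its fully numeric allele list.

    Generic codes substitute the final field; allele-specific codes replace
    the last two fields with each stored pair — when the stored first field
    disagrees with the typed one, the code wins and a :class:`MacWarning` is
    emitted, never a silent override.
    """
    star = name_with_code.find("*")
    raw_fields = name_with_code[star + 1 :].split(":") if star >= 0 else []
    for f in raw_fields[:-1]:
        if _CODE_RE.match(f):
            raise MacStructureError(
                f"MAC {f!r} in non-final field position in {name_with_code!r}"
            )
    name = parse_allele_name(name_with_code, allow_mac=True)
    if name.mac is None:
        raise MacStructureError(
            f"{name_with_code!r} carries no MAC in its final field"
        )
    entry = table.entries.get(name.mac)
    if entry is None:
        raise UnknownMacError(
            f"MAC {name.mac!r} not present in the supplied code table"
        )

    out: list[AlleleName] = []
    if entry.allele_specific:
        if len(name.fields) < 2:
            raise MacStructureError(
                f"allele-specific MAC {entry.code} needs a typed first field in "
                f"{name_with_code!r}"
            )
        typed_first = name.fields[-2]
        firsts = {e.split(":")[0] for e in entry.expansions}
        if firsts != {typed_first}:
            warnings.warn(
                f"allele-specific MAC {entry.code} overrides typed first field "
                f"{typed_first!r} with {sorted(firsts)}",
                MacWarning,
                stacklevel=2,
            )
        for pair in entry.expansions:
            first, second = pair.split(":")
            fields = name.fields[:-2] + (first, second)
            out.append(AlleleName(prefix=name.prefix, gene=name.gene, fields=fields))
    else:
        for final in entry.expansions:
            fields = name.fields[:-1] + (final,)
            out.append(AlleleName(prefix=name.prefix, gene=name.gene, fields=fields))
    return out


def contains_mac(text: str) -> bool:
    """True iff any leaf of *text* (an allele name or whole GL String) has a
    MAC-shaped final field."""
    return _MAC_FIELD_RE.search(text) is not None
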