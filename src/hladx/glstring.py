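"""Genotype List (GL) Strings: parsing, serialization, interrogation, expansion.

A GL String encodes every layer of ambiguity a genotyping result can carry in
a single line of text, using five delimiters in fixed precedence from loosest
to tightest binding:

    ``^``  joins locus blocks into a multilocus genotype
    ``|``  separates alternative genotypes within a locus block
    ``+``  joins the haplotypes (gene copies) of one genotype
    ``~``  joins phased allele lists within one haplotype
    ``/``  separates ambiguous alleles within one allele list

so ``HLA-A*01:01+HLA-A*02:01^HLA-B*07:02+HLA-B*08:01`` is two locus blocks,
each an unambiguous genotype of two haplotypes, and
``HLA-DRB1*14:01/HLA-DRB1*14:54`` is a single allele list that cannot be
resolved between two alleles identical over the antigen recognition domain.

A GL String Code (GLSC) wraps a GL String with its reference context —
gene-family namespace and database release — as ``namespace#version#glstring``,
because allele names are only meaningful relative to the release that defined
them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Optional

from .nomenclature import (
    AlleleName,
    NomenclatureError,
    ReleaseVersion,
    parse_allele_name,
)

__all__ = [
    "AlleleList",
    "Haplotype",
    "Genotype",
    "LocusBlock",
    "MultilocusGenotype",
    "GlAst",
    "GlCode",
    "GlParseError",
    "GlConsistencyError",
    "ExpansionOverflowError",
    "GlStringWarning",
    "DELIMITERS",
    "parse_glstring",
    "serialize_glstring",
    "enumerate_genotypes",
    "parse_glcode",
    "serialize_glcode",
    "loci_of",
    "iter_leaves",
]

#: Delimiters in precedence order, loosest first.
DELIMITERS = ("^", "|", "+", "~", "/")

DEFAULT_EXPANSION_CAP = 10_000


class GlParseError(ValueError):
    """Malformed GL String or GL String Code."""


class GlConsistencyError(ValueError):
    """Structurally valid GL String violating a cross-leaf contract."""


class ExpansionOverflowError(ValueError):
    """Genotype expansion would exceed the configured cap."""


class GlStringWarning(UserWarning):
    pass


@dataclass(frozen=True)
class AlleleList:
    alleles: tuple[AlleleName, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise GlParseError("empty allele list")


@dataclass(frozen=True)
class Haplotype:
    allele_lists: tuple[AlleleList, ...]

    def __post_init__(self) -> None:
        if not self.allele_lists:
            raise GlParseError("empty haplotype")


@dataclass(frozen=True)
class Genotype:
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise GlParseError("empty genotype")


@dataclass(frozen=True)
class LocusBlock:
    genotypes: tuple[Genotype, ...]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise GlParseError("empty locus block")


@dataclass(frozen=True)
class MultilocusGenotype:
    blocks: tuple[LocusBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise GlParseError("empty GL String")


GlAst = MultilocusGenotype


@dataclass(frozen=True)
class GlCode:
    """A GL String with its reference context (namespace + release)."""

    namespace: str
    version: ReleaseVersion
    payload: GlAst

    def __post_init__(self) -> None:
        if not self.namespace or not self.namespace.islower() or not self.namespace.isalnum():
            raise GlParseError(
                f"namespace must be a nonempty lowercase token, got {self.namespace!r}"
            )


def _split(text: str, delim: str, base: int) -> Iterator[tuple[str, int]]:
    """Split on *delim* yielding (segment, absolute offset); empty segments
    are grammar errors."""
    offset = base
    for seg in text.split(delim):
        if not seg:
            raise GlParseError(
                f"empty segment before {delim!r} at character {offset}"
            )
        yield seg, offset
        offset += len(seg) + 1


def parse_glstring(
    text: str,
    *,
    allow_mac: bool = False,
    allow_unofficial: bool = False,
    strict_whitespace: bool = True,
) -> GlAst:
    """Parse a GL String into its nested ambiguity structure.

    Whitespace inside a GL String is illegal; with
    ``strict_whitespace=False`` it is stripped with a warning instead.
    Leaf names are parsed strictly unless MAC or unofficial-group forms are
    explicitly admitted (validation workflows separate grammar validity from
    nomenclature officialdom).
    """
    if not text:
        raise GlParseError("empty GL String")
    if any(c.isspace() for c in text):
        if strict_whitespace:
            raise GlParseError(
                f"whitespace at character {next(i for i, c in enumerate(text) if c.isspace())}"
            )
        warnings.warn("stripping whitespace from GL String", GlStringWarning, stacklevel=2)
        text = "".join(text.split())

    def leaf(seg: str, off: int) -> AlleleName:
        try:
            return parse_allele_name(
                seg, allow_mac=allow_mac, allow_unofficial=allow_unofficial
            )
        except NomenclatureError as exc:
            raise GlParseError(f"invalid allele name at character {off}: {exc}") from exc

    blocks = []
    for block_text, b_off in _split(text, "^", 0):
        genotypes = []
        for geno_text, g_off in _split(block_text, "|", b_off):
            haplotypes = []
            for hap_text, h_off in _split(geno_text, "+", g_off):
                lists = []
                for list_text, l_off in _split(hap_text, "~", h_off):
                    alleles = tuple(
                        leaf(a, a_off) for a, a_off in _split(list_text, "/", l_off)
                    )
                    lists.append(AlleleList(alleles))
                haplotypes.append(Haplotype(tuple(lists)))
            genotypes.append(Genotype(tuple(haplotypes)))
        blocks.append(LocusBlock(tuple(genotypes)))
    return MultilocusGenotype(tuple(blocks))


def serialize_glstring(ast: GlAst) -> str:
    """Canonical text of an AST; exact inverse of :func:`parse_glstring`.

    Order is preserved at every level — alternatives and alleles appear on
    the wire exactly as authored, never sorted.
    """
    return "^".join(
        "|".join(
            "+".join(
                "~".join(
                    "/".join(str(a) for a in al.alleles) for al in hap.allele_lists
                )
                for hap in geno.haplotypes
            )
            for geno in block.genotypes
        )
        for block in ast.blocks
    )


def _genotype_size(geno: Genotype) -> int:
    return math.prod(
        len(al.alleles) for hap in geno.haplotypes for al in hap.allele_lists
    )


def enumerate_genotypes(
    ast: GlAst, locus_index: int = 0, *, cap: int = DEFAULT_EXPANSION_CAP
) -> list[str]:
    """Expand all ambiguity at one locus into unambiguous genotype strings.

    Performs the Cartesian expansion of every allele list across every
    genotype alternative, then deduplicates under unordered-genotype
    normalization (a+b and b+a are the same diploid genotype; haplotypes are
    sorted lexicographically for comparison and output).  Raises
    :class:`ExpansionOverflowError` when the raw expansion would exceed
    *cap* — never a silent truncation.
    """
    try:
        block = ast.blocks[locus_index]
    except IndexError:
        raise IndexError(
            f"locus index {locus_index} out of range for {len(ast.blocks)} blocks"
        ) from None
    total = sum(_genotype_size(g) for g in block.genotypes)
    if total > cap:
        raise ExpansionOverflowError(
            f"expansion size {total} exceeds cap {cap}; raise the cap explicitly "
            "to proceed"
        )
    out: list[str] = []
    seen: set[str] = set()
    for geno in block.genotypes:
        hap_choices = [
            [
                "~".join(combo)
                for combo in product(
                    *[[str(a) for a in al.alleles] for al in hap.allele_lists]
                )
            ]
            for hap in geno.haplotypes
        ]
        for combo in product(*hap_choices):
            key = "+".join(sorted(combo))
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def parse_glcode(
    text: str, *, allow_mac: bool = False, allow_unofficial: bool = False
) -> GlCode:
    """Parse ``namespace#version#glstring`` into a :class:`GlCode`."""
    parts = text.split("#")
    if len(parts) != 3:
        raise GlParseError(
            f"GL String Code needs exactly 3 '#'-separated parts, got {len(parts)}"
        )
    namespace, version_text, payload = parts
    try:
        version = ReleaseVersion.parse(version_text)
    except NomenclatureError as exc:
        raise GlParseError(f"bad version in GL String Code: {exc}") from exc
    ast = parse_glstring(payload, allow_mac=allow_mac, allow_unofficial=allow_unofficial)
    return GlCode(namespace=namespace, version=version, payload=ast)


def serialize_glcode(code: GlCode) -> str:
    return f"{code.namespace}#{code.version}#{serialize_glstring(code.payload)}"


def iter_leaves(ast: GlAst) -> Iterator[AlleleName]:
    for block in ast.blocks:
        for geno in block.genotypes:
            for hap in geno.haplotypes:
                for al in hap.allele_lists:
                    yield from al.alleles


def loci_of(ast: GlAst, *, strict: bool = True) -> list[Optional[str]]:
    """Gene symbol of each locus block, in block order.

    A block whose leaves mix gene symbols is a consistency error: raised when
    *strict*, reported as ``None`` for that block otherwise (validation rules
    use the lenient form to flag rather than crash).
    """
    out: list[Optional[str]] = []
    for i, block in enumerate(ast.blocks):
        genes = {
            a.gene
            for geno in block.genotypes
            for hap in geno.haplotypes
            for al in hap.allele_lists
            for a in al.alleles
        }
        if len(genes) != 1:
            if strict:
                raise GlConsistencyError(
                    f"locus block {i} mixes gene symbols {sorted(genes)}"
                )
            out.append(None)
        else:
            out.append(genes.pop())
    return out
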