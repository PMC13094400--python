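"""Seeded synthetic-data generators and bundled reference fixtures.

Everything here exists so that every stage of the toolkit is testable with
no external download: a seeded GL String generator spanning the full
ambiguity grammar, a seeded minimal-HML message generator with per-rule
defect injection for negative testing, and the transcribed golden example
message (reference cell line IHW9224, typing center NUTTT, transplant
center NLUT1, release 3.57.0).

Generated messages draw allele names from the bundled toy catalog, so
catalog-membership validation passes by construction unless the
unknown-allele defect is requested.  The generator seed is recorded in each
message as a sample property for provenance.  The generators emulate the
*structure* of exchanged messages, not population genetics: allele draws
are uniform, with no linkage or frequency realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .glstring import parse_glstring, serialize_glstring
from .hml import AlleleAssignment, Header, HmlMessage, Sample, Typing, TypingMethod
from .nomenclature import load_catalog, parse_allele_name

__all__ = [
    "GeneratorConfig",
    "FixtureError",
    "gen_glstring",
    "gen_hml",
    "golden_figure3",
    "toy_catalog_path",
    "toy_mac_table_path",
    "golden_xml_path",
    "golden_json_path",
    "KNOWN_DEFECTS",
]

_DATA = Path(__file__).parent / "data"


class FixtureError(ValueError):
    pass


def toy_catalog_path() -> Path:
    return _DATA / "toy_catalog.tsv"


def toy_mac_table_path() -> Path:
    return _DATA / "toy_mac_table.tsv"


def golden_xml_path() -> Path:
    return _DATA / "golden_minimal.xml"


def golden_json_path() -> Path:
    return _DATA / "golden_minimal.json"


KNOWN_DEFECTS = ("M1", "M2", "M3", "M4", "M5", "G1", "G2", "G3", "O1", "O2")


@dataclass(frozen=True)
class GeneratorConfig:
    """Ambiguity profile and defect menu for the synthetic generators.

    The ambiguity bounds are inclusive maxima; each generated structure draws
    its actual dimensions uniformly within them.  ``defects`` names
    validation rules to violate by targeted mutation.
    """

    seed: int = 0
    loci: tuple[str, ...] = ("A", "B", "DRB1")
    max_allele_list: int = 3
    max_alternatives: int = 2
    phase_depth: int = 2
    defects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for d in self.defects:
            if d not in KNOWN_DEFECTS:
                raise FixtureError(
                    f"unknown defect {d!r}; known: {', '.join(KNOWN_DEFECTS)}"
                )
        if min(self.max_allele_list, self.max_alternatives, self.phase_depth) < 1:
            raise FixtureError("ambiguity bounds must be >= 1")


def _allele_pools() -> dict[str, list[str]]:
    catalog = load_catalog(toy_catalog_path())
    pools: dict[str, list[str]] = {}
    for name in catalog.entries:
        gene = parse_allele_name(name).gene
        pools.setdefault(gene, []).append(name)
    return pools


def _gen_block(rng: random.Random, pool: list[str], cfg: GeneratorConfig) -> str:
    def allele_list() -> str:
        k = rng.randint(1, min(cfg.max_allele_list, len(pool)))
        return "/".join(rng.sample(pool, k))

    def haplotype() -> str:
        depth = rng.randint(1, cfg.phase_depth) if rng.random() < 0.4 else 1
        return "~".join(allele_list() for _ in range(depth))

    def genotype() -> str:
        return "+".join(haplotype() for _ in range(2))

    n_alt = rng.randint(1, cfg.max_alternatives)
    return "|".join(genotype() for _ in range(n_alt))


def gen_glstring(cfg: GeneratorConfig) -> str:
    """One multilocus GL String (a block per configured locus) that parses
    cleanly and stays within the configured ambiguity bounds."""
    rng = random.Random(cfg.seed)
    pools = _allele_pools()
    blocks = []
    for locus in cfg.loci:
        pool = pools.get(locus)
        if not pool:
            raise FixtureError(f"no toy-catalog alleles for locus {locus!r}")
        blocks.append(_gen_block(rng, pool, cfg))
    text = "^".join(blocks)
    # canonical by construction; assert cheaply that it parses
    return serialize_glstring(parse_glstring(text))


_CONSENSUS_ALPHABET = "ACGT"


def gen_hml(cfg: GeneratorConfig) -> HmlMessage:
    """A minimal-HML message that passes every tier with an empty defect
    menu; with defect *d* injected it fails exactly rule *d* among the
    minimal rules."""
    rng = random.Random(cfg.seed)
    pools = _allele_pools()
    sample_id = f"SAMPLE-{rng.randrange(10**6):06d}"
    sample = Sample(
        sample_id=sample_id,
        properties={
            "lab-ref": "LAB01",
            "tc-ref": "TC001",
            "patient-ref": f"PAT{rng.randrange(10**6):06d}",
            "generator-seed": str(cfg.seed),
        },
    )
    for locus in cfg.loci:
        pool = pools.get(locus)
        if not pool:
            raise FixtureError(f"no toy-catalog alleles for locus {locus!r}")
        glstring = _gen_block(rng, pool, cfg)
        consensus = "".join(rng.choice(_CONSENSUS_ALPHABET) for _ in range(60))
        sample.typings.append(
            Typing(
                gene_family="HLA",
                assignment=AlleleAssignment(
                    allele_db="IPD-IMGT/HLA",
                    allele_version="3.57.0",
                    date="2024-11-20",
                    glstring=glstring,
                ),
                method=TypingMethod(
                    description="NGS amplicon typing with phased consensus assembly",
                    platform="generic-ngs",
                    exons_targeted=[2, 3],
                    software="hladx-sim",
                    software_version="0.1",
                ),
                consensus=consensus,
            )
        )
    msg = HmlMessage(
        header=Header(
            message_id=f"MSG-{cfg.seed:08d}",
            created="2025-01-01T00:00:00Z",
            reporting_center="LAB01",
        ),
        samples=[sample],
    )
    for defect in cfg.defects:
        _inject_defect(msg, defect)
    return msg


def _inject_defect(msg: HmlMessage, defect: str) -> None:
    sample = msg.samples[0]
    typing = sample.typings[0]
    if defect == "M1":
        sample.properties.pop("patient-ref", None)
    elif defect == "M2":
        sample.properties.pop("lab-ref", None)
    elif defect == "M3":
        typing.assignment.allele_version = "not-a-version"
    elif defect == "M4":
        typing.assignment.glstring = typing.assignment.glstring + "/"
    elif defect == "M5":
        typing.assignment.glstring = "HLA-A*01:01g+HLA-A*02:01:01:01"
    elif defect == "G1":
        for t in sample.typings:
            t.method = None
    elif defect == "G2":
        typing.gene_family = "KIR"
    elif defect == "G3":
        typing.assignment.glstring = "HLA-A*99:98+HLA-A*02:01:01:01"
    elif defect == "O1":
        for t in sample.typings:
            t.consensus = None
    elif defect == "O2":
        typing.assignment.glstring = "HLA-A*01:AB+HLA-A*02:01:01:01"
    else:  # pragma: no cover - guarded by GeneratorConfig
        raise FixtureError(f"unknown defect {defect!r}")


def golden_figure3() -> HmlMessage:
    """The transcribed golden example message: reference cell line IHW9224
    typed against IPD-IMGT/HLA release 3.57.0, reported by typing center
    NUTTT to transplant center NLUT1 with no typing method (the typing was
    taken from the database, not re-run)."""

    def typing(glstring: str) -> Typing:
        return Typing(
            gene_family="HLA",
            assignment=AlleleAssignment(
                allele_db="IPD-IMGT/HLA",
                allele_version="3.57.0",
                date="2024-11-20",
                glstring=glstring,
            ),
        )

    sample = Sample(
        sample_id="IHW9224",
        properties={
            "lab-ref": "NUTTT",
            "tc-ref": "NLUT1",
            "patient-ref": "IHW9224",
        },
        typings=[
            typing("HLA-A*01:01:01:01+HLA-A*02:01:01:01"),
            typing("HLA-B*07:02:01:01+HLA-B*08:01:01:01"),
            typing("HLA-DRB1*14:01:01/HLA-DRB1*14:54:01+HLA-DRB1*15:01:01:01"),
        ],
    )
    return HmlMessage(
        header=Header(
            message_id="NUTTT-IHW9224-001",
            created="2024-11-20T00:00:00Z",
            reporting_center="NUTTT",
        ),
        samples=[sample],
    )
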