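"""GL String grammar: parsing, serialization, expansion and reference codes."""

import itertools
import math

import pytest

from hladx.fixtures import GeneratorConfig, gen_glstring
from hladx.glstring import (
    ExpansionOverflowError,
    GlConsistencyError,
    GlParseError,
    GlStringWarning,
    enumerate_genotypes,
    iter_leaves,
    loci_of,
    parse_glcode,
    parse_glstring,
    serialize_glcode,
    serialize_glstring,
)
from hladx.nomenclature import ReleaseVersion


class TestParse:
    def test_ambiguity_pair_is_one_allele_list(self):
        ast = parse_glstring("HLA-DRB1*14:01/HLA-DRB1*14:54")
        assert len(ast.blocks) == 1
        block = ast.blocks[0]
        assert len(block.genotypes) == 1
        geno = block.genotypes[0]
        assert len(geno.haplotypes) == 1
        hap = geno.haplotypes[0]
        assert len(hap.allele_lists) == 1
        assert len(hap.allele_lists[0].alleles) == 2

    def test_single_allele_degenerate_nesting(self):
        ast = parse_glstring("HLA-A*01:01:01:01")
        assert [len(b.genotypes) for b in ast.blocks] == [1]
        assert len(list(iter_leaves(ast))) == 1

    def test_two_locus_blocks_of_two_haplotypes(self):
        ast = parse_glstring("HLA-A*01:01+HLA-A*02:01^HLA-B*07:02+HLA-B*08:01")
        assert len(ast.blocks) == 2
        for block in ast.blocks:
            assert len(block.genotypes) == 1
            assert len(block.genotypes[0].haplotypes) == 2

    @pytest.mark.parametrize(
        "text", ["", "HLA-A*01:01/", "/HLA-A*01:01", "HLA-A*01:01^^HLA-B*07:02"]
    )
    def test_empty_segments_rejected(self, text):
        with pytest.raises(GlParseError):
            parse_glstring(text)

    def test_parse_error_carries_character_offset(self):
        with pytest.raises(GlParseError, match="character 12"):
            parse_glstring("HLA-A*01:01+bogus")

    def test_whitespace_strict_vs_lenient(self):
        with pytest.raises(GlParseError, match="whitespace"):
            parse_glstring("HLA-A*01:01 +HLA-A*02:01")
        with pytest.warns(GlStringWarning):
            ast = parse_glstring(
                "HLA-A*01:01 +HLA-A*02:01", strict_whitespace=False
            )
        assert serialize_glstring(ast) == "HLA-A*01:01+HLA-A*02:01"


class TestSerialize:
    def test_single_allele_verbatim(self):
        assert serialize_glstring(parse_glstring("HLA-A*01:01:01:01")) == "HLA-A*01:01:01:01"

    def test_alternative_order_preserved_not_sorted(self):
        text = "HLA-B*08:01+HLA-B*07:02|HLA-B*07:02+HLA-B*44:02"
        assert serialize_glstring(parse_glstring(text)) == text

    @pytest.mark.parametrize("seed", range(25))
    def test_round_trip_on_generated_strings(self, seed):
        text = gen_glstring(GeneratorConfig(seed=seed))
        ast = parse_glstring(text)
        assert serialize_glstring(ast) == text
        assert parse_glstring(serialize_glstring(ast)) == ast


def _oracle_expansions(ast, locus_index):
    """Independent brute-force Cartesian expansion with unordered-genotype
    deduplication."""
    out = set()
    for geno in ast.blocks[locus_index].genotypes:
        hap_options = []
        for hap in geno.haplotypes:
            lists = [[str(a) for a in al.alleles] for al in hap.allele_lists]
            hap_options.append(["~".join(c) for c in itertools.product(*lists)])
        for combo in itertools.product(*hap_options):
            out.add("+".join(sorted(combo)))
    return out


class TestEnumerate:
    def test_two_by_two_shape_gives_four(self):
        ast = parse_glstring("HLA-A*01:01/HLA-A*01:02+HLA-A*02:01/HLA-A*03:01")
        assert len(enumerate_genotypes(ast)) == 4

    def test_unambiguous_genotype_gives_one(self):
        ast = parse_glstring("HLA-A*01:01+HLA-A*02:01")
        assert enumerate_genotypes(ast) == ["HLA-A*01:01+HLA-A*02:01"]

    def test_identical_lists_deduplicate_to_three(self):
        ast = parse_glstring("HLA-A*01:01/HLA-A*01:02+HLA-A*01:01/HLA-A*01:02")
        assert sorted(enumerate_genotypes(ast)) == [
            "HLA-A*01:01+HLA-A*01:01",
            "HLA-A*01:01+HLA-A*01:02",
            "HLA-A*01:02+HLA-A*01:02",
        ]

    def test_cap_overflow_is_explicit(self):
        text = "+".join(
            ["/".join(f"HLA-A*{i:02d}:01" for i in range(1, 11))] * 2
        )
        ast = parse_glstring(text)
        with pytest.raises(ExpansionOverflowError):
            enumerate_genotypes(ast, cap=50)
        assert len(enumerate_genotypes(ast, cap=100)) == 55  # C(10,2)+10

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        ast = parse_glstring(gen_glstring(GeneratorConfig(seed=seed)))
        for i in range(len(ast.blocks)):
            got = enumerate_genotypes(ast, i)
            assert set(got) == _oracle_expansions(ast, i)
            assert len(got) == len(set(got))

    def test_count_law_upper_bound(self):
        # count <= sum over alternatives of product of list sizes, with
        # equality when every leaf is distinct
        ast = parse_glstring("HLA-A*01:01/HLA-A*01:02+HLA-A*02:01/HLA-A*03:01")
        raw = sum(
            math.prod(len(al.alleles) for h in g.haplotypes for al in h.allele_lists)
            for g in ast.blocks[0].genotypes
        )
        assert len(enumerate_genotypes(ast)) == raw

    def test_bad_locus_index(self):
        with pytest.raises(IndexError):
            enumerate_genotypes(parse_glstring("HLA-A*01:01"), 3)


class TestGlCode:
    def test_parse_parts(self):
        code = parse_glcode("hla#3.57.0#HLA-A*01:01:01:01")
        assert code.namespace == "hla"
        assert code.version == ReleaseVersion(3, 57, 0)
        assert len(list(iter_leaves(code.payload))) == 1

    def test_round_trip(self):
        text = "hla#3.57.0#HLA-DRB1*14:01/HLA-DRB1*14:54"
        assert serialize_glcode(parse_glcode(text)) == text

    @pytest.mark.parametrize(
        "text",
        ["3.57.0#HLA-A*01:01", "hla#3.57.0#HLA-A*01:01#extra", "hla#vX#HLA-A*01:01"],
    )
    def test_arity_and_version_errors(self, text):
        with pytest.raises(GlParseError):
            parse_glcode(text)


class TestLoci:
    def test_block_order(self):
        ast = parse_glstring("HLA-A*01:01+HLA-A*02:01^HLA-B*07:02+HLA-B*08:01")
        assert loci_of(ast) == ["A", "B"]

    def test_single_allele(self):
        assert loci_of(parse_glstring("HLA-A*01:01")) == ["A"]

    def test_mixed_block_is_a_consistency_error(self):
        ast = parse_glstring("HLA-A*01:01+HLA-B*07:02")
        with pytest.raises(GlConsistencyError):
            loci_of(ast)
        assert loci_of(ast, strict=False) == [None]


def test_delimiter_precedence_matches_sequential_split():
    """Splitting ^ then | then + then ~ then / reproduces the parsed AST."""
    for seed in range(10):
        text = gen_glstring(GeneratorConfig(seed=seed))
        ast = parse_glstring(text)
        split_view = [
            [
                [
                    [al.split("/") for al in hap.split("~")]
                    for hap in geno.split("+")
                ]
                for geno in block.split("|")
            ]
            for block in text.split("^")
        ]
        ast_view = [
            [
                [
                    [[str(a) for a in al.alleles] for al in hap.allele_lists]
                    for hap in geno.haplotypes
                ]
                for geno in block.genotypes
            ]
            for block in ast.blocks
        ]
        assert split_view == ast_view
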