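"""Allele-name parsing, catalog lookup and release-version/branch mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hladx.nomenclature import (
    AlleleCatalog,
    AlleleName,
    LookupStatus,
    NomenclatureError,
    NomenclatureWarning,
    ReleaseVersion,
    branch_to_version,
    parse_allele_name,
    resolution_of,
    validate_against_catalog,
    version_to_branch,
)


class TestParseAlleleName:
    @pytest.mark.parametrize(
        "text, gene, fields, expr, group",
        [
            ("HLA-A*01:01:01:01", "A", ("01", "01", "01", "01"), None, None),
            ("HLA-DRB1*14:54", "DRB1", ("14", "54"), None, None),
            ("HLA-A*01", "A", ("01",), None, None),
            ("HLA-A*01:01:01:02N", "A", ("01", "01", "01", "02"), "N", None),
            ("HLA-A*01:01:01G", "A", ("01", "01", "01"), None, "G"),
            ("HLA-B*07:02P", "B", ("07", "02"), None, "P"),
        ],
    )
    def test_structured_parse(self, text, gene, fields, expr, group):
        name = parse_allele_name(text)
        assert name.gene == gene
        assert name.fields == fields
        assert name.expression_suffix == expr
        assert name.group_suffix == group
        assert str(name) == text  # canonical round trip

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("HLA-A*01:01:01:01:01", "5 > 4"),
            ("HLA-A*01::01", "empty field"),
            ("HLA-A*01:0x", "unknown suffix"),
            ("HLA-A*xx:01", "non-digit field"),
            ("HLA-A-01:01", "missing '*'"),
            ("HLA-A*01:01g", "little-g"),
            ("HLA-A*01:AB", "multiple-allele code"),
            ("", "empty"),
            ("HLA-A* 01:01", "whitespace"),
        ],
    )
    def test_malformed_names_name_the_offender(self, text, fragment):
        with pytest.raises(NomenclatureError, match=fragment):
            parse_allele_name(text)

    def test_prefixless_name_normalized_with_warning(self):
        with pytest.warns(NomenclatureWarning):
            name = parse_allele_name("A*01:01")
        assert str(name) == "HLA-A*01:01"

    def test_lenient_modes_flag_rather_than_reject(self):
        mac = parse_allele_name("HLA-A*01:AB", allow_mac=True)
        assert mac.mac == "AB" and not mac.is_official
        g = parse_allele_name("HLA-A*01:01g", allow_unofficial=True)
        assert g.unofficial_group and not g.is_official
        assert str(g) == "HLA-A*01:01g"

    def test_group_suffix_needs_two_fields(self):
        with pytest.raises(NomenclatureError, match="two-field"):
            parse_allele_name("HLA-A*01G")

    def test_leading_zeros_are_significant(self):
        a = parse_allele_name("HLA-A*01:01")
        b = AlleleName(prefix="HLA", gene="A", fields=("1", "1"))
        assert str(a) != str(b)


@pytest.mark.parametrize(
    "text, expected",
    [("HLA-DRB1*14:54", 2), ("HLA-A*01:01:01:01", 4), ("HLA-A*01", 1)],
)
def test_resolution_is_field_count(text, expected):
    assert resolution_of(parse_allele_name(text)) == expected


# strategy for official names: the canonical serialization must survive a
# parse/format round trip
_names = st.builds(
    AlleleName,
    prefix=st.just("HLA"),
    gene=st.sampled_from(["A", "B", "C", "DRB1", "DQB1", "DPB1"]),
    fields=st.lists(
        st.integers(0, 999).map(lambda n: f"{n:02d}"), min_size=2, max_size=4
    ).map(tuple),
    expression_suffix=st.sampled_from([None, "N", "L", "S", "C", "A", "Q"]),
    group_suffix=st.just(None),
)


@settings(max_examples=200, deadline=None)
@given(_names)
def test_parse_format_round_trip(name):
    assert parse_allele_name(str(name)) == name


class TestCatalog:
    def test_worked_identifier_pair(self, catalog):
        result = validate_against_catalog(
            parse_allele_name("HLA-A*01:01:01:01"), catalog
        )
        assert result.status is LookupStatus.FOUND
        assert result.accession == "HLA00001"

    def test_absent_name_is_not_found(self, catalog):
        result = validate_against_catalog(parse_allele_name("HLA-A*99:99"), catalog)
        assert result.status is LookupStatus.NOT_FOUND
        assert not result

    def test_identity_sweep(self, catalog):
        for name, accession in catalog.entries.items():
            result = validate_against_catalog(parse_allele_name(name), catalog)
            assert result.accession == accession

    def test_finer_than_catalog_is_a_distinct_outcome(self, catalog):
        # catalog holds HLA-DRB1*14:01:01 (3 fields); query 4 fields
        result = validate_against_catalog(
            parse_allele_name("HLA-DRB1*14:01:01:99"), catalog
        )
        assert result.status is LookupStatus.UNKNOWN_AT_RESOLUTION

    def test_ambiguity_pair_flagged_ard_identical(self, catalog):
        assert (
            catalog.metadata["HLA-DRB1*14:01:01"]["ard_identical"]
            == "HLA-DRB1*14:54:01"
        )
        assert (
            catalog.metadata["HLA-DRB1*14:54:01"]["ard_identical"]
            == "HLA-DRB1*14:01:01"
        )

    def test_duplicate_accessions_rejected_on_load(self):
        with pytest.raises(NomenclatureError, match="accession"):
            AlleleCatalog(
                release=ReleaseVersion(3, 57, 0),
                entries={"HLA-A*01:01": "HLA00001", "HLA-A*01:02": "HLA00001"},
            )

    def test_release_header(self, catalog):
        assert catalog.release == ReleaseVersion(3, 57, 0)


class TestVersionBranch:
    def test_documented_pair(self):
        assert version_to_branch(ReleaseVersion.parse("3.57.0")) == "3570"
        assert branch_to_version("3570") == ReleaseVersion(3, 57, 0)

    @pytest.mark.parametrize(
        "version, branch", [("3.9.0", "390"), ("3.0.0", "300"), ("3.57.0", "3570")]
    )
    def test_concatenation_rule(self, version, branch):
        assert version_to_branch(ReleaseVersion.parse(version)) == branch
        assert branch_to_version(branch) == ReleaseVersion.parse(version)

    def test_round_trip_brute_force_sweep(self):
        # exhaustive over major 1..5, minor 0..99, patch 0..9 (5,000 versions)
        for major in range(1, 6):
            for minor in range(100):
                for patch in range(10):
                    v = ReleaseVersion(major, minor, patch)
                    assert branch_to_version(version_to_branch(v)) == v

    @pytest.mark.parametrize("branch", ["35a0", "30", "35700", ""])
    def test_degenerate_branches_rejected(self, branch):
        with pytest.raises(NomenclatureError):
            branch_to_version(branch)

    def test_version_text_round_trip(self):
        v = ReleaseVersion.parse("3.57.0")
        assert str(v) == "3.57.0"
        with pytest.raises(NomenclatureError):
            ReleaseVersion.parse("3.57")
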