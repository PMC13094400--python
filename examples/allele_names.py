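"""Parse WHO allele names, look them up in a release catalog, and map
release versions to repository branches."""

from hladx import (
    ReleaseVersion,
    branch_to_version,
    load_catalog,
    parse_allele_name,
    resolution_of,
    validate_against_catalog,
    version_to_branch,
)
from hladx.fixtures import toy_catalog_path

name = parse_allele_name("HLA-A*01:01:01:01")
print(f"{name} -> gene {name.gene}, {resolution_of(name)}-field resolution")
# four fields means the typing resolves the full genomic sequence variant

catalog = load_catalog(toy_catalog_path())
result = validate_against_catalog(name, catalog)
print(f"catalog release {catalog.release}: {name} -> accession {result.accession}")
# the accession is the release-stable database identifier for this allele

pair = ["HLA-DRB1*14:01:01", "HLA-DRB1*14:54:01"]
for text in pair:
    partner = catalog.metadata[text]["ard_identical"]
    print(f"{text} is ARD-identical to {partner}")
# identical antigen-recognition-domain exons: indistinguishable unless typing
# extends beyond exon 2, which is why this pair is the classic ambiguity

version = ReleaseVersion.parse("3.57.0")
branch = version_to_branch(version)
print(f"release {version} <-> repository branch {branch} "
      f"(round trip: {branch_to_version(branch)})")
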