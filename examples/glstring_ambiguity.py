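"""Parse a GL String, inspect its structure, and expand its ambiguity."""

from hladx import enumerate_genotypes, loci_of, parse_glcode, parse_glstring

# one DRB1 genotype whose first copy is ambiguous between two
# ARD-identical alleles
text = "HLA-DRB1*14:01/HLA-DRB1*14:54+HLA-DRB1*15:01"
ast = parse_glstring(text)
print(f"loci: {loci_of(ast)}")
for genotype in enumerate_genotypes(ast):
    print(f"  possible genotype: {genotype}")
# 2 expansions: the reported result is consistent with either allele call

multi = "HLA-A*01:01+HLA-A*02:01^HLA-B*07:02+HLA-B*08:01"
ast = parse_glstring(multi)
print(f"multilocus string covers loci {loci_of(ast)} "
      f"in {len(ast.blocks)} blocks")

# a GL String Code pins the string to the database release that defined it
code = parse_glcode("hla#3.57.0#HLA-DRB1*14:01/HLA-DRB1*14:54")
print(f"namespace={code.namespace} version={code.version}: interpretation is "
      "only valid against that release")
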