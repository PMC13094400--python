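# Toy allele catalog: a ~20-entry stand-in for a full IPD-IMGT/HLA release
# export (synthetic subset; accession pairings beyond HLA-A*01:01:01:01 are
# illustrative).  Format: release-version header line, then
# name<TAB>accession[<TAB>key=value;...]
3.57.0
HLA-A*01:01:01:01	HLA00001
HLA-A*01:02	HLA00002
HLA-A*02:01:01:01	HLA00005
HLA-A*03:01:01:01	HLA00037
HLA-A*11:01:01:01	HLA00043
HLA-A*24:02:01:01	HLA00050
HLA-A*01:01:01:02N	HLA02558
HLA-B*07:02:01:01	HLA00132
HLA-B*08:01:01:01	HLA00146
HLA-B*27:05:02	HLA00225
HLA-B*44:02:01:01	HLA00318
HLA-C*07:01:01:01	HLA00433
HLA-C*07:02:01:01	HLA00434
HLA-DRB1*14:01:01	HLA00674	ard_identical=HLA-DRB1*14:54:01
HLA-DRB1*14:54:01	HLA01929	ard_identical=HLA-DRB1*14:01:01
HLA-DRB1*15:01:01:01	HLA00865
HLA-DRB1*03:01:01:01	HLA00671
HLA-DRB1*04:01:01:01	HLA00685
HLA-DQB1*06:02:01:01	HLA00646
HLA-DQB1*02:01:01:01	HLA00622
HLA-DPB1*04:01:01:01	HLA00521
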