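# Toy multiple-allele-code table (synthetic; the real NMDP registry is
# external).  Format: code<TAB>'/'-joined expansions[<TAB>*] where the '*'
# marks an allele-specific code whose expansions are first:second pairs.
AB	01/02
AC	01/03
BD	02/03/04
XX	01:01/02:05	*
JKL	01:01/01:02	*
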