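# Synthetic stand-in for the OMIM-derived panel of genes with reported
# dominant and/or de novo pathogenic variants, used to restrict the
# heterozygous-variant filter in single-patient non-consanguineous families.
MFN2
C10ORF2
BICD2
DNA2
ACTA1
PURA
DYNC1H1
CTNNB1
WDR45
CASK
KIF1A
SCN2A
STXBP1
GNAO1
KCNQ2
DNM1L
OPA1
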