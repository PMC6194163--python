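# Synthetic stand-in for the MitoCarta mitochondria-localized gene inventory.
# Contains the panel-member causal genes of the packaged cohort plus filler
# entries; membership drives the per-gene MitoCarta flag.
AARS2
SERAC1
SPG7
FBXL4
MTFMT
NDUFAF4
QRSL1
SLC25A46
COQ7
NDUFAF5
TMEM126A
PYCR2
POLG1
NDUFS7
MTO1
NDUFA12
KARS
NDUFV2
TMEM126B
TRMU
ATPAF2
AMACR
C12ORF65
MFN2
C10ORF2
CLPP
SLC25A32
ACAD8
DNA2
NDUFS1
NDUFS4
SDHA
SURF1
COX10
OPA1
TFAM
TYMP
SUCLA2
MPV17
ETFDH
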