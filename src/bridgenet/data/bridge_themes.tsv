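# Default functional-theme assignment for bridge endpoints. A bridge is
# tallied under a theme when both endpoints belong to it; themes are not
# mutually exclusive.
gene	theme
FN1	inflammation_ecm
UMOD	inflammation_ecm
TNF	inflammation_ecm
IL6	inflammation_ecm
IL1B	inflammation_ecm
ACE	metabolic_ras
INS	metabolic_ras
TNF	metabolic_ras
IL6	metabolic_ras
APOA1	lipid_protein_homeostasis
SNCA	lipid_protein_homeostasis
INS	lipid_protein_homeostasis
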