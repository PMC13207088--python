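# Printed cross-disease bridge edges (CKD gene, PD gene) with per-channel
# evidence scores and published combined confidence scores.
gene_a	gene_b	experimental	database	textmining	coexpression	neighborhood	fusion	cooccurrence	combined_score
FN1	TNF	0.057	0	0	0	0	0	0	0.970
APOA1	INS	0.127	0	0.400	0	0	0	0	0.906
FN1	IL6	0.087	0	0	0	0	0	0	0.900
APOA1	SNCA	0.067	0.510	0.400	0	0	0	0	0.883
FN1	IL1B	0.055	0.051	0	0	0	0	0	0.869
UMOD	IL1B	0.057	0	0	0	0	0	0	0.850
ACE	INS	0.052	0	0	0	0	0	0	0.849
FN1	AKT1	0.055	0	0	0	0	0	0	0.846
WT1	IGF2	0.044	0	0	0	0	0	0	0.812
ACE	IL6	0	0	0.400	0	0	0	0	0.776
FN1	SOD1	0.053	0	0	0	0	0	0	0.773
ACE	TNF	0.044	0	0	0	0	0	0	0.720
FN1	MAPK1	0	0	0.500	0	0	0	0	0.716
UMOD	TNF	0.060	0.071	0	0	0	0	0	0.707
FN1	INS	0.055	0	0	0	0	0	0	0.701
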