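# Published TPM values for the lead bridge genes in the tissues the analysis
# contrasts (brain substantia nigra vs. kidney cortex, plus liver for APOA1).
gene	tissue	tpm
SNCA	substantia_nigra	20.81
SNCA	kidney_cortex	1.59
APOA1	kidney_cortex	0.77
APOA1	liver	200.0
APOA1	substantia_nigra	0.52
UMOD	kidney_cortex	1000.0
UMOD	substantia_nigra	0.01
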