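EXOCARTA_EXOSOME	synthetic extracellular-vesicle cargo catalog (exosome compartment)	APOA1	SNCA	FN1	CD9	CD63	CD81	HSPA8	TSG101	ALIX	FLOT1
VESICLEPEDIA_SEV	synthetic small-extracellular-vesicle catalog	APOA1	SNCA	UMOD	CD9	CD63	ANXA2	GAPDH	ACTB
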