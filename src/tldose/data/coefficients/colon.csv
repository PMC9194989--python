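segment,mass_fraction,provenance
ascending,0.25,ICRP 23-style large-intestine segment mass fractions
transverse,0.30,ICRP 23-style large-intestine segment mass fractions
descending,0.20,ICRP 23-style large-intestine segment mass fractions
sigmoid,0.15,ICRP 23-style large-intestine segment mass fractions
rectum,0.10,ICRP 23-style large-intestine segment mass fractions
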