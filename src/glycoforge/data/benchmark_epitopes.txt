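# Benchmark annotated MUC1 glycopeptide epitopes (Tn on one site each)
RPAPGS(GalNAc)TAPPAHG
PAHGVT(GalNAc)SAPD
PAHGVTS(GalNAc)APD
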