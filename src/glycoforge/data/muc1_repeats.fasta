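>MUC1_TR_phase_RP MUC1 20-aa tandem-repeat unit, RPAP... phase
RPAPGSTAPPAHGVTSAPDT
>MUC1_TR_phase_HG MUC1 20-aa tandem-repeat unit, HGVT... phase
HGVTSAPDTRPAPGSTAPPA
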