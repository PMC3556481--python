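antibody,analyte,ka_per_M_s,kd_per_s,KD_printed_nM,chi2_RU2
16A,RPAPGS(Ac3GalNAc)TAPPAHG,5.721E+4,0.02794,488.5,18.6
16A,RPAPGS(GalNAc)TAPPAHG,3.353E+4,0.03120,930.4,23.1
16A,RPAPGSTAPPAHG,7208,0.003898,540.8,4.95
14A,RPAPGS(Ac3GalNAc)TAPPAHG,1.600E+5,0.07362,460.2,10.3
14A,RPAPGS(GalNAc)TAPPAHG,1.172E+5,0.05141,438.6,19.4
14A,RPAPGSTAPPAHG,1.218E+4,0.002851,234.0,3.35
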