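# glycan alphabet: tn-stn
# state 0 (UNOCCUPIED) is implicit; order = digit order
GalNAc	C8H13NO5
NeuAc-GalNAc	C8H13NO5+C11H17NO8
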