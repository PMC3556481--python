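# glycan alphabet: tn
# state 0 (UNOCCUPIED) is implicit; order = digit order
GalNAc	C8H13NO5
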