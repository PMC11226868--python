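name	site	cut_offset
SspI	AATATT	3
EcoRI	GAATTC	1
HindIII	AAGCTT	1
DraI	TTTAAA	3
EcoRV	GATATC	3
XbaI	TCTAGA	1
PstI	CTGCAG	5
HinfI	GANTC	1
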