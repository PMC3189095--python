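# Type IIP restriction enzymes used by the BglBrick/pBb platform.
# cut_top / cut_bottom are 0-based offsets into the recognition hexamer:
# the top strand is cut before recognition[cut_top], the bottom strand
# before (in top-strand coordinates) recognition[cut_bottom].
# name	recognition	cut_top	cut_bottom
EcoRI	GAATTC	1	5
BglII	AGATCT	1	5
BamHI	GGATCC	1	5
XhoI	CTCGAG	1	5
AatII	GACGTC	5	1
AvrII	CCTAGG	1	5
SpeI	ACTAGT	1	5
SacI	GAGCTC	5	1
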