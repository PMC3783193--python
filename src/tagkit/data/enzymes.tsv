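name	recognition	cut_top	cut_bottom
NotI	GCGGCCGC	2	6
AscI	GGCGCGCC	2	6
HindIII	AAGCTT	1	5
XhoI	CTCGAG	1	5
SalI	GTCGAC	1	5
EcoRI	GAATTC	1	5
BamHI	GGATCC	1	5
BglII	AGATCT	1	5
MluI	ACGCGT	1	5
SpeI	ACTAGT	1	5
AvrII	CCTAGG	1	5
SnaBI	TACGTA	3	3
EcoRV	GATATC	3	3
SmaI	CCCGGG	3	3
PstI	CTGCAG	5	1
SacI	GAGCTC	5	1
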