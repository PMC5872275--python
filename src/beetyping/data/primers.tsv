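name	seq	direction	mutagenic	mutated_positions
LepF1	ATTCAACCAATCATAAAGATATTGG	forward	0
LepR1	TAAACTTCTGGATGTCCAAAAAATCA	reverse	0
AmCarp-f	AGATATTGGGATCTTGTA	forward	0
AmCar-r	CAGCTAATACAGGTAATGA	reverse	0
CYTB-f	TATGTACTACCATGAGGACAAATATC	forward	0
CYTB-r	ATTACACCTCCTAATTTATTAGGAAT	reverse	0
AmCar-f	ATTTCMTCAATTATAGGATCATTAAAYTTACC	forward	1	32
AmCarp-r	CTAGTAACAATTGTATTATAAATTTGATCAGCG	reverse	1	33
AmEu1-f	GGATGAACAGTATATCCACC	forward	0
AmEu1-r	GTAACTATTAAGTTTAATGATCCTATAATAGC	reverse	1	32
AmEu2-f	CTTTAATACTAGGATCACCTGATATAGCGAT	forward	1	31
AmEu2-r	CTGATAATGGTGGATATA	reverse	0
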