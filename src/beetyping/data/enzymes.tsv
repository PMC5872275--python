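name	site	cut_offset	isoschizomers
AluI	AGCT	2	AluBI
HinfI	GANTC	1
HspAI	GCGC	1	HinP1I,AspLEI,BstHHI,CfoI,GlaI,Hin6I
MspI	CCGG	1	HpaII,BsiSI,HapII
DraI	TTTAAA	3
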