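haplotype	AluI	HinfI	HspAI	MspI
mellifera_H1	cut	uncut	uncut	uncut
mellifera_H2	uncut	cut	uncut	uncut
carpatica	uncut	uncut	cut	uncut
carnica	uncut	uncut	cut	cut
caucasica	uncut	uncut	uncut	uncut
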