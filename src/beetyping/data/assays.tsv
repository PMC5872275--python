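assay	fwd_primer	rev_primer	enzyme	targets	cut_fragments	uncut_length
AmEu1	AmEu1-f	AmEu1-r	AluI	mellifera_H1	107,32	139
AmEu2	AmEu2-f	AmEu2-r	HinfI	mellifera_H2	122,28	150
AmCarp	AmCarp-f	AmCarp-r	HspAI	carpatica,carnica	111,30	141
AmCar	AmCar-f	AmCar-r	MspI	carnica	118,30	148
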