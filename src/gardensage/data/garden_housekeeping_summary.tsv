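gene	top_mean	middle_mean	bottom_mean	p_printed
elongation factor 1-beta	142	157	160	0.80
eukaryotic translation initiation factor 1	110	110	111	1.0
glyceraldehyde 3-phosphate dehydrogenase	156	128	115	0.12
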