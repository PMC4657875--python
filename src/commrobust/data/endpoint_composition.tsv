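# Percent composition of the static nine-member community at 72 h determined by
# differential plating, for the full mix (+Cg) and the community lacking
# Chryseobacterium gleum (-Cg). Standard deviations of three replicates in the
# sd columns. Columns sum to ~100 up to printed rounding.
species	abbrev	pct_full_mix	sd_full_mix	pct_minus_cg	sd_minus_cg
Ralstonia pickettii	Rp	5.9	0.9	4.5	0.3
Cupriavidus metallidurans	Cm	1.0	0.5	1.3	0.8
Chryseobacterium gleum	Cg	27.7	2.1	0	0
Ralstonia insidiosa	Ri	18.7	2.8	19.6	4.2
Sphingomonas sanguinis	Ss	4.4	1.5	7.4	0.8
Burkholderia multivorans	Bm	17.7	1.4	21.9	2.2
Phyllobacterium myrsianacearum	Pm	4.0	4.0	1.4	0.2
Sphingomonas paucimobilis	Sp	9.3	2.3	15.7	2.2
Burkholderia cepacia	Bc	11.1	1.7	28.1	2.1
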