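# Differential susceptibility of the nine ISS potable-water isolates on LB agar
# after 48 h. Growth codes: ++ normal growth compared to no selection; + slow
# growth (colonies less than half the no-selection size); - no apparent growth.
# Supplements: NS = LB no-salt + 5% sucrose (no selection); Cb100 carbenicillin
# 100 ug/ml; Ct200 cetrimide 200 ug/ml; Tp100 trimethoprim 100 ug/ml; Gm25
# gentamicin 25 ug/ml; Km100 kanamycin 100 ug/ml. P. myrsianacearum grows
# exceedingly slowly without selection at 37 C and is encoded as no growth there.
species	abbrev	temp_c	NS	Cb100	Ct200	Tp100	Gm25	Km100	colony_class
Ralstonia pickettii	Rp	37	++	++	-	+	-	-	white
Ralstonia pickettii	Rp	30	++	++	-	-	+	-	white
Cupriavidus metallidurans	Cm	37	++	-	-	-	-	++	white
Cupriavidus metallidurans	Cm	30	++	+	-	-	++	++	white
Chryseobacterium gleum	Cg	37	++	-	-	-	-	++	orange
Chryseobacterium gleum	Cg	30	++	-	-	+	++	++	orange
Ralstonia insidiosa	Ri	37	++	++	-	-	++	+	white_rough
Ralstonia insidiosa	Ri	30	++	++	-	-	+	+	white_rough
Sphingomonas sanguinis	Ss	37	++	-	-	++	-	-	yellow
Sphingomonas sanguinis	Ss	30	++	++	-	+	-	-	yellow
Burkholderia multivorans	Bm	37	++	++	++	-	+	+	white
Burkholderia multivorans	Bm	30	++	++	++	-	++	+	white
Phyllobacterium myrsianacearum	Pm	37	-	-	-	-	-	-	white
Phyllobacterium myrsianacearum	Pm	30	++	-	-	++	-	-	white
Sphingomonas paucimobilis	Sp	37	++	++	-	++	-	-	yellow
Sphingomonas paucimobilis	Sp	30	++	++	-	++	-	-	yellow
Burkholderia cepacia	Bc	37	++	+	-	++	+	-	white
Burkholderia cepacia	Bc	30	++	-	-	+	++	-	white
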