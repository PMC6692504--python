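clade	species	n_species	second_locus_context	mechanism
Nadsonia_fulvescens_elongata	Nadsonia_fulvescens_elongata	1	telomere	introgression_gain
Blastobotrys_proliferans	Blastobotrys_proliferans	1	telomere	introgression_gain
Kuraishia_molischiana	Kuraishia_molischiana	1	telomere	introgression_gain
Yamadazyma	Yamadazyma_nakazawae;Yamadazyma_philogaea	2	telomere	introgression_gain
Wickerhamia_fluorescens	Wickerhamia_fluorescens	1	telomere	introgression_gain
Saccharomycopsis_capsularis	Saccharomycopsis_capsularis	1	telomere	introgression_gain
Lipomyces_oligophaga_suomiensis	Lipomyces_oligophaga;Lipomyces_suomiensis	2	telomere	introgression_gain
Kazachstania_rosinii	Kazachstania_rosinii	1	telomere	introgression_gain
Peterozyma	Peterozyma_xylosa;Peterozyma_toletana	2	rdna	introgression_gain
Kazachstania_africana	Kazachstania_africana	1	telomere	rearrangement
Lipomyces_japonicus	Lipomyces_japonicus	1	internal	unknown
Ambrosiozyma	Ambrosiozyma_ambrosiae;Ambrosiozyma_philentoma	2	internal	unknown
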