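species	category	provisional
Candida_arabinofermentans	HET	false
Candida_succiphila	HET	false
Ogataea_glucozyma	FF1	false
Ogataea_henricii	FF1	false
Ogataea_kodamae	FF1	false
Ogataea_methanolica	FF1	false
Ogataea_methylivora	HET	false
Ogataea_minuta	FF1	false
Ogataea_naganishii	PHC	false
Ogataea_nitratoaversa	HET	false
Ogataea_nonfermentans	FF1	false
Ogataea_parapolymorpha	FF1	false
Ogataea_philodendri	FF1	false
Ogataea_pilisensis	FF1	false
Ogataea_pini	FF1	false
Ogataea_polymorpha	FF1	false
Ogataea_populialbae	FF1	false
Ogataea_ramenticola	HET	false
Ogataea_trehaloabstinens	FF1	false
Ogataea_trehalophila	FF1	false
Ogataea_zsoltii	FF1	false
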