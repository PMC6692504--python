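species	category	provisional
Ascoidea_asiatica	HET	false
Ascoidea_rubescens	FF1	false
Barnettozyma_californica	PHC	false
Brettanomyces_anomalus	HET	false
Candida_arabinofermentans	HET	false
Candida_succiphila	HET	false
Cyberlindnera_jadinii	HET	false
Cyberlindnera_mrakii	FF1	false
Cyberlindnera_saturnus	FF1	false
Cyberlindnera_suaveolens	FF1	false
Hanseniaspora_uvarum	HET	false
Kloeckera_hatyaiensis	HET	false
Kluyveromyces_lactis	3LOC	false
Komagataella_phaffii	FF2	false
Komagataella_populi	FF2	false
Komagataella_pseudopastoris	FF2	false
Kregervanrija_delftensis	FF1	false
Kregervanrija_fluxuum	FF1	false
Nakazawaea_holstii	HET	false
Nakazawaea_peltata	HET	false
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
Pachysolen_tannophilus	FF1	false
Peterozyma_toletana	PHN	false
Peterozyma_xylosa	PHN	false
Phaffomyces_opuntiae	HET	false
Pichia_kudriavzevii	HET	false
Saccharomyces_cerevisiae	3LOC	false
Saccharomycopsis_capsularis	PHN	false
Saccharomycopsis_malanga	HET	false
Saturnispora_besseyi	HET	false
Saturnispora_dispora	FF2	false
Saturnispora_hagleri	FF2	false
Saturnispora_mendoncae	HET	false
Saturnispora_serradocipensis	FF2	false
Saturnispora_silvae	HET	false
Saturnispora_zaruensis	FF2	false
Starmera_quercuum	FF1	false
Wickerhamomyces_canadensis	FF2	true
Wickerhamomyces_hampshirensis	PHC	false
Wickerhamomyces_sp_YB2243	HET	false
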