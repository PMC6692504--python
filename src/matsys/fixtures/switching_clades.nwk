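((((Ascoidea_asiatica,Ascoidea_rubescens),(Saccharomycopsis_malanga,Saccharomycopsis_capsularis)),(Pachysolen_tannophilus,((Nakazawaea_peltata,Nakazawaea_holstii),(Peterozyma_xylosa,Peterozyma_toletana)))),((((Cyberlindnera_jadinii,(Cyberlindnera_saturnus,(Cyberlindnera_mrakii,Cyberlindnera_suaveolens))),((Starmera_quercuum,Phaffomyces_opuntiae),((Wickerhamomyces_canadensis,Wickerhamomyces_sp_YB2243),(Wickerhamomyces_hampshirensis,Barnettozyma_californica)))),((Hanseniaspora_uvarum,Kloeckera_hatyaiensis),(Saccharomyces_cerevisiae,Kluyveromyces_lactis))),(((Pichia_kudriavzevii,(Komagataella_phaffii,(Komagataella_pseudopastoris,Komagataella_populi))),(Brettanomyces_anomalus,(Kregervanrija_fluxuum,Kregervanrija_delftensis))),((Saturnispora_mendoncae,(Saturnispora_silvae,(Saturnispora_besseyi,((Saturnispora_zaruensis,Saturnispora_hagleri),(Saturnispora_dispora,Saturnispora_serradocipensis))))),((Ogataea_naganishii,(Ogataea_methylivora,Ogataea_ramenticola)),(Candida_succiphila,((Ogataea_polymorpha,(Ogataea_parapolymorpha,(Ogataea_nonfermentans,(Ogataea_philodendri,(Ogataea_kodamae,(Ogataea_minuta,(Ogataea_henricii,(Ogataea_pini,(Ogataea_glucozyma,(Ogataea_zsoltii,(Ogataea_trehaloabstinens,Ogataea_populialbae))))))))))),(((Ogataea_trehalophila,Ogataea_methanolica),Candida_arabinofermentans),(Ogataea_pilisensis,Ogataea_nitratoaversa)))))))));
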