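((Ogataea_naganishii,(Ogataea_methylivora,Ogataea_ramenticola)),(Candida_succiphila,((Ogataea_polymorpha,(Ogataea_parapolymorpha,(Ogataea_nonfermentans,(Ogataea_philodendri,(Ogataea_kodamae,(Ogataea_minuta,(Ogataea_henricii,(Ogataea_pini,(Ogataea_glucozyma,(Ogataea_zsoltii,(Ogataea_trehaloabstinens,Ogataea_populialbae))))))))))),(((Ogataea_trehalophila,Ogataea_methanolica),Candida_arabinofermentans),(Ogataea_pilisensis,Ogataea_nitratoaversa)))));
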