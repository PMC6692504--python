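(((Kluyveromyces_lactis,(Kluyveromyces_marxianus,(Kluyveromyces_dobzhanskii,Kluyveromyces_aestuarii))),((Lachancea_kluyveri,(Lachancea_thermotolerans,(Lachancea_waltii,(Lachancea_fantastica,(Lachancea_quebecensis,(Lachancea_lanzarotensis,(Lachancea_fermentati,(Lachancea_cidri,(Lachancea_meyersii,(Lachancea_mirantina,(Lachancea_dasiensis,Lachancea_nothofagi))))))))))),(Ashbya_aceri,(Eremothecium_gossypii,(Eremothecium_cymbalariae,(Eremothecium_coryli,Eremothecium_sinecaudum)))))),(((Zygosaccharomyces_rouxii,(Zygosaccharomyces_bailii,(Zygosaccharomyces_bisporus,Zygosaccharomyces_kombuchaensis))),((Zygotorulaspora_mrakii,Zygotorulaspora_florentina),(Torulaspora_delbrueckii,(Torulaspora_pretoriensis,(Torulaspora_franciscae,(Torulaspora_microellipsoides,Torulaspora_maleeae)))))),(Vanderwaltozyma_polyspora,(Yueomyces_sinensis,((Tetrapisispora_phaffii,(Tetrapisispora_blattae,(Tetrapisispora_fleetii,Tetrapisispora_iriomotensis))),((Naumovozyma_castellii,Naumovozyma_dairenensis),((Kazachstania_unispora,((Kazachstania_africana,(Kazachstania_taianensis,Kazachstania_bromeliacearum)),((Kazachstania_rosinii,(Kazachstania_servazzii,Kazachstania_solicola)),((Kazachstania_yakushimaensis,Kazachstania_transvaalensis),(Kazachstania_kunashirensis,(Kazachstania_martiniae,(Kazachstania_naganishii,(Kazachstania_aerobia,(Kazachstania_spencerorum,(Kazachstania_turicensis,(Kazachstania_viticola,Kazachstania_intestinalis))))))))))),((Candida_glabrata,(Candida_nivariensis,(Candida_bracarensis,(Candida_castellii,(Nakaseomyces_bacillisporus,Nakaseomyces_delphensis))))),(Saccharomyces_cerevisiae,(Saccharomyces_paradoxus,(Saccharomyces_mikatae,(Saccharomyces_jurei,(Saccharomyces_kudriavzevii,(Saccharomyces_arboricola,(Saccharomyces_eubayanus,Saccharomyces_uvarum)))))))))))))));
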