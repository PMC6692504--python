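species	category	provisional
Ashbya_aceri	3LOC	false
Candida_bracarensis	3LOC	false
Candida_castellii	3LOC	false
Candida_glabrata	3LOC	false
Candida_nivariensis	3LOC	false
Eremothecium_coryli	3LOC	false
Eremothecium_cymbalariae	3LOC	false
Eremothecium_gossypii	3LOC	false
Eremothecium_sinecaudum	3LOC	false
Kazachstania_aerobia	3LOC	false
Kazachstania_africana	PHN	false
Kazachstania_bromeliacearum	3LOC	false
Kazachstania_intestinalis	3LOC	false
Kazachstania_kunashirensis	3LOC	false
Kazachstania_martiniae	3LOC	false
Kazachstania_naganishii	3LOC	false
Kazachstania_rosinii	PHN	false
Kazachstania_servazzii	3LOC	false
Kazachstania_solicola	3LOC	false
Kazachstania_spencerorum	3LOC	false
Kazachstania_taianensis	3LOC	false
Kazachstania_transvaalensis	HET	false
Kazachstania_turicensis	3LOC	false
Kazachstania_unispora	3LOC	false
Kazachstania_viticola	3LOC	false
Kazachstania_yakushimaensis	HET	false
Kluyveromyces_aestuarii	3LOC	false
Kluyveromyces_dobzhanskii	3LOC	false
Kluyveromyces_lactis	3LOC	false
Kluyveromyces_marxianus	3LOC	false
Lachancea_cidri	3LOC	false
Lachancea_dasiensis	3LOC	false
Lachancea_fantastica	3LOC	false
Lachancea_fermentati	3LOC	false
Lachancea_kluyveri	HET	false
Lachancea_lanzarotensis	3LOC	false
Lachancea_meyersii	3LOC	false
Lachancea_mirantina	3LOC	false
Lachancea_nothofagi	3LOC	false
Lachancea_quebecensis	3LOC	false
Lachancea_thermotolerans	3LOC	false
Lachancea_waltii	3LOC	false
Nakaseomyces_bacillisporus	3LOC	false
Nakaseomyces_delphensis	3LOC	false
Naumovozyma_castellii	3LOC	false
Naumovozyma_dairenensis	3LOC	false
Saccharomyces_arboricola	3LOC	false
Saccharomyces_cerevisiae	3LOC	false
Saccharomyces_eubayanus	3LOC	false
Saccharomyces_jurei	3LOC	false
Saccharomyces_kudriavzevii	3LOC	false
Saccharomyces_mikatae	3LOC	false
Saccharomyces_paradoxus	3LOC	false
Saccharomyces_uvarum	3LOC	false
Tetrapisispora_blattae	3LOC	false
Tetrapisispora_fleetii	3LOC	false
Tetrapisispora_iriomotensis	3LOC	false
Tetrapisispora_phaffii	3LOC	false
Torulaspora_delbrueckii	3LOC	false
Torulaspora_franciscae	3LOC	false
Torulaspora_maleeae	3LOC	false
Torulaspora_microellipsoides	3LOC	false
Torulaspora_pretoriensis	3LOC	false
Vanderwaltozyma_polyspora	3LOC	false
Yueomyces_sinensis	3LOC	false
Zygosaccharomyces_bailii	3LOC	false
Zygosaccharomyces_bisporus	3LOC	false
Zygosaccharomyces_kombuchaensis	3LOC	false
Zygosaccharomyces_rouxii	3LOC	false
Zygotorulaspora_florentina	3LOC	false
Zygotorulaspora_mrakii	3LOC	false
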