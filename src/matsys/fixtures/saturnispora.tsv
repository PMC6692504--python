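species	category	provisional
Saturnispora_besseyi	HET	false
Saturnispora_dispora	FF2	false
Saturnispora_hagleri	FF2	false
Saturnispora_mendoncae	HET	false
Saturnispora_serradocipensis	FF2	false
Saturnispora_silvae	HET	false
Saturnispora_zaruensis	FF2	false
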