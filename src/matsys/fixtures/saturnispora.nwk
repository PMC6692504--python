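(Saturnispora_mendoncae,(Saturnispora_silvae,(Saturnispora_besseyi,((Saturnispora_zaruensis,Saturnispora_hagleri),(Saturnispora_dispora,Saturnispora_serradocipensis)))));
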