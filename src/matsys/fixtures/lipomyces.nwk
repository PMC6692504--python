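((Lipomyces_oligophaga,Lipomyces_suomiensis),((Lipomyces_doorenjongii,Lipomyces_lipofer),(Lipomyces_japonicus,(Lipomyces_starkeyi,(Lipomyces_arxii,(Lipomyces_mesembrius,Lipomyces_kononenkoae))))));
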