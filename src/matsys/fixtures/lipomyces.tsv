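species	category	provisional
Lipomyces_arxii	PHC	false
Lipomyces_doorenjongii	HET	false
Lipomyces_japonicus	PHN	false
Lipomyces_kononenkoae	PHC	false
Lipomyces_lipofer	PHC	false
Lipomyces_mesembrius	PHC	false
Lipomyces_oligophaga	PHN	false
Lipomyces_starkeyi	PHC	false
Lipomyces_suomiensis	PHN	false
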