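>MATa1|mat_core|toy
NRWNEEMPWFCPHKWTPQSGWCKSHKMVKWYGVKVLEPICDAADAIALQKSEHTFYVSNP
FWCPHIPQAGTSCMRKHCKHITLCCAAEWAEKFDGNESRDTGSEPMGQEKSRSYSVFGRI
VCYCSRYN
>MATa2|mat_core|toy
DNTDNDQYRVSNELTTGVRLGLDMIHTTREHDLQFLEMLFCVFELSCEPSKANERPTMRD
YCYDNASVWPLRPRNWSDDWHGGRRQLAGIQAWIHVVITDFVLYTLGTPSCGSLQHVSID
ELEWTAIDMCGLLLKIRNIHAV
>MATalpha1|mat_core|toy
WQATKFFNVNQKGQGDRGSQPLACGVGEIWCDYWICTRIQRVWEHPHDHASSHASCMHMH
QIRFSHMDFCMENQYERAEAHCKMYRMNKARHLMWHARWCLWYFWHCGSKYQWHSCDIGS
FYSYLSPNRNTYEEQVSLWKMPSPGHICDHYKHKCL
>MATalpha2|mat_core|toy
PGDMEMNEDFIHTYLSLICHDMPFRQECYFGATVKMYELGNTIFSVSLNATGQFILMHTY
NTLCQVHGPKGCDGTPTIIYNYVMPKFDGKPCMVSCNVFVSQVFDIARQPNKYCRYPKYK
AARTVRWCHVKITY
>SLA2|neighbor|toy
LHGVRMNIKPCPNAGEHWHTIVRFNHPRVGNIMLSTLRSMQERNFLYCDPNVDPTVDHRH
AAFHQGKCRYDFPGMVHMKRYAQLMVLKCKDLNVAEFANLYTHSNVNPFMYRFNESKPWS
RFYAPMMFHDLRRRWHQWHMWMVLFFPQNIPTHQQVEMHMQGEKYTHTHH
>DIC1|neighbor|toy
VCFHSGSDLDWHSHVNCSMHEYGGHTGWPEWNDYIGMNEHMMLILTRAKPQIIEAYYMWH
DHPESQHCEEALFEHMPYCEKTYERRDKITDCKLAYHDDMSAMLVGITCIVLGGACKPHD
YQVVMETHTKLPMEGMCPVITEPECDRQ
>APN2|neighbor|toy
PEWRSYLKMMFDVVKDNDAPAESPNCVDEFIFFDNIMGPNRNMYFMGQTTGQDQLTTFFS
NQSWKCGCSNWVCPRPMNARKKDSHNMTVRECFCMKTKSKLEVFMLCTYEWIIGVHMMCT
VASPDKCVAHEVIGQCIDICMQSIWSDRPGQVQANFKARS
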