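# The 20 study Brassicaceae species and their 3-letter codes.
species	code
Arabidopsis halleri	Aha
Arabidopsis lyrata	Aly
Arabis alpina	Aal
Barbarea vulgaris	Bvu
Boechera stricta	Bst
Brassica cretica	Bcr
Camelina sativa	Csa
Capsella grandiflora	Cgr
Capsella bursa-pastoris	Cbp
Capsella rubella	Cru
Cardamine hirsuta	Chi
Eutrema salsugineum	Esa
Leavenworthia alabamica	Lal
Lepidium meyenii	Lme
Raphanus raphanistrum	Rra
Raphanus sativus	Rsa
Sinapis alba	Sal
Sisymbrium irio	Sir
Schrenkiella parvula	Spa
Thlaspi arvense	Tar
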