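# The 49 curated cloned Brassicaceae disease resistance (R) genes used as
# homology references: curated RGA subclass, database accession(s) and
# pathogen(s) recognised. alias records an alternative printed name for the
# same gene (the Bna_MAPk / Bna_MPK9 naming drift); which of the two is
# canonical is not established, so both are accepted on lookup.
gene	subclass	accession	alias	pathogens
At_ADR1	NL	Q9FW44		Hyaloperonospora arabidopsidis;Erysiphe cichoracearum;Pseudomonas syringae
At_BAK1	LRR-RLK	Q94F62		Pseudomonas syringae;Sclerotinia sclerotiorum
At_FLS2	LRR-RLK	Q9FL28		Pseudomonas syringae
At_NDR1	TM	O48915		Pseudomonas syringae
At_NRG1a	RNL	Q9FKZ1		Albugo candida;Hyaloperonospora arabidopsidis;Pseudomonas syringae
At_NRG1b	RNL	Q9FKZ0		Albugo candida;Hyaloperonospora arabidopsidis;Pseudomonas syringae
At_PBS1	Other-RLK	Q9FE20		Pseudomonas syringae
At_RAC1	TNL	Q6QX58		Albugo candida
At_RFO1	Other-RLK	Q8RY17		Fusarium oxysporum matthioli
At_RFO2	LRR-RLP	Q9SHI4		Fusarium oxysporum matthioli
At_RFO3	Other-RLK	Q9LW83		Fusarium oxysporum matthioli
At_RIN4	CC	Q8GYN5		Pseudomonas syringae
At_RLM1a	TNL	F4I594		Leptosphaeria maculans
At_RLM1b	TNL	Q9CAK1		Leptosphaeria maculans
At_RLM3	TN	Q9FT77		Leptosphaeria maculans;Botrytis cinerea;Alternaria brassicicola;Alternaria brassicae
At_RLP1	LRR-RLP	Q9LNV9		Xanthomonas spp.
At_RLP23	LRR-RLP	O48849		Sclerotinia sclerotiorum
At_RLP30	LRR-RLP	Q9MA83		Pseudomonas syringae;Sclerotinia sclerotiorum
At_RLP32	LRR-RLP	Q9M9X0		Pseudomonas syringae
At_RLP42	LRR-RLP	Q9LJS0		Botrytis cinerea;Hyaloperonospora arabidopsidis
At_RPM1	NL	Q39214		Pseudomonas syringae
At_RPP1	TNL	F4J339		Hyaloperonospora arabidopsidis
At_RPP13	CNL	Q9M667		Hyaloperonospora arabidopsidis
At_RPP2a	TNL	F4JT78		Hyaloperonospora arabidopsidis
At_RPP2b	TNL	F4JT80		Hyaloperonospora arabidopsidis
At_RPP39	CNL	H9BPR9		Hyaloperonospora arabidopsidis
At_RPP4	TNL	F4JNA9		Hyaloperonospora arabidopsidis
At_RPP5	TNL	F4JNB7		Hyaloperonospora arabidopsidis
At_RPP7	NL	Q8W3K0		Hyaloperonospora arabidopsidis
At_RPP8	CNL	Q8W4J9		Hyaloperonospora arabidopsidis
At_RPS2	NL	Q42484		Pseudomonas syringae
At_RPS4	TNL	Q9XGM3		Pseudomonas syringae
At_RPS5	TNL	O64973		Pseudomonas syringae
At_Rpw8.1	RNL	Q9C5Z7		Erysiphe cichoracearum
At_Rpw8.2	RNL	Q9C5Z6		Erysiphe cichoracearum
At_RRS1	TNL	P0DKH5		Pseudomonas syringae
At_SOBIR1	LRR-RLK	Q9SKB2		Pseudomonas syringae;Sclerotinia sclerotiorum
At_WRR12	TNL	MK034462		Albugo candida
At_WRR4a	TNL	Q9C7X0		Albugo candida
At_WRR4b	TNL	MK034466		Albugo candida
At_WRR8	TNL	MK034463		Albugo candida
At_WRR9	NL	MK034464		Albugo candida
Bju_WRR1	CNL	A0A0B5L618		Albugo candida
Bna_LepR3/Rlm2	LRR-RLP	I7C3X3/A0A0B5L618		Leptosphaeria maculans
Bna_MAPk	Other-RLK	A0A078IFE9	Bna_MPK9	Leptosphaeria maculans
Bna_Rlm9/4/7	Other-RLK	CDX67982.1		Leptosphaeria maculans
Bol_FocBo1	TNL	BAQ21734.1		Fusarium oxysporum f. sp. conglutinans
Bra_cRa/cRb	TNL	M5A8J3		Plasmodiophora brassicae
Bra_Crr1a	TNL	AB605024.1		Plasmodiophora brassicae
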