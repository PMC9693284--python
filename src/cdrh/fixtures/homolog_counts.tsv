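# Per-reference-gene homolog counts across the 20 study proteomes.
# retained = homologs whose RGA subclass equals the reference subclass;
# diversified = semicolon list of "subclass:count" for homologs with a
# different subclass; diversified_total = printed parenthesised total;
# total = printed row total. The At_RRS1 row prints a diversified total of
# 15 with no composition ("0 (15)"): it is kept opaque (empty breakdown,
# opaque=1), never guessed.
# The printed grand-total row is retained=1992, diversified=1181,
# total=3172; the per-row diversified entries sum to 1180 (a documented
# one-unit inconsistency in the source table).
gene	ref_subclass	retained	diversified	diversified_total	total	opaque
At_ADR1	NL	33	CNL:5;NBS:6;TNL:1	12	45	0
At_BAK1	LRR-RLK	117	Other-RLK:2	2	119	0
At_FLS2	LRR-RLK	24		0	24	0
At_NDR1	TM	0		0	0	0
At_NRG1a	RNL	0	CNL:31;NL:28;LRR-RLP:1;CN:3;NBS:3	66	66	0
At_NRG1b	RNL	0	CNL:31;NL:26;LRR-RLP:1;CN:3;NBS:3	64	64	0
At_PBS1	Other-RLK	20		0	20	0
At_RAC1	TNL	48	NL:10;NBS:3;TN:13;TX:6;Other-NLR:1	33	81	0
At_RFO1	Other-RLK	119		0	119	0
At_RFO2	LRR-RLP	31	LRR-RLK:28	28	59	0
At_RFO3	Other-RLK	50		0	50	0
At_RIN4	CC	0		0	0	0
At_RLM1a	TNL	61	NBS:5;NL:12;Other-NLR:9;TN:16;TX:38	80	141	0
At_RLM1b	TNL	81	NBS:4;NL:23;Other-NLR:8;TN:16;TX:31;LRR-RLP:1	83	164	0
At_RLM3	TN	5	NL:3;NBS:2;Other-NLR:1;TNL:7;TX:4	17	22	0
At_RLP1	LRR-RLP	36		0	36	0
At_RLP23	LRR-RLP	117		0	117	0
At_RLP30	LRR-RLP	47		0	47	0
At_RLP32	LRR-RLP	159	LRR-RLK:1	1	160	0
At_RLP42	LRR-RLP	112		0	112	0
At_RPM1	NL	14	LRR-RLP:1;NBS:1	2	16	0
At_RPP1	TNL	26	CNL:1;Other-NLR:22;NBS:2;NL:6;TN:15;TX:30	76	102	0
At_RPP13	CNL	14	NBS:4;CN:1;NL:16	21	35	0
At_RPP2a	TNL	56	NL:19;Other-NLR:9;TN:7;TX:7	42	98	0
At_RPP2b	TNL	20	CNL:1;NBS:2;NL:3;Other-NLR:4	10	30	0
At_RPP39	CNL	71	CN:11;NBS:3;NL:26;LRR-RLP:3	43	114	0
At_RPP4	TNL	8	NL:3;Other-NLR:2;TN:5;TX:5	15	23	0
At_RPP5	TNL	8	NL:2;Other-NLR:3;TN:6;TX:11	22	30	0
At_RPP7	NL	56	CN:1;CNL:12;LRR-RLP:1;NBS:10	24	80	0
At_RPP8	CNL	80	CN:12;NBS:6;NL:24	42	122	0
At_RPS2	NL	6	CNL:18;NBS:3	21	27	0
At_RPS4	TNL	32	NBS:1;NL:6;Other-NLR:7	14	46	0
At_RPS5	TNL	0	CNL:58;CN:6;NBS:7;NL:22	93	93	0
At_Rpw8.1	RNL	0		0	0	0
At_Rpw8.2	RNL	0		0	0	0
At_RRS1	TNL	26		15	41	1
At_SOBIR1	LRR-RLK	26	Other-RLK:1	1	27	0
At_WRR12	TNL	29	NL:5;TX:2;LRR-RLP:4	11	40	0
At_WRR4a	TNL	37	NL:4;Other-NLR:4;TN:6;TX:33	47	84	0
At_WRR4b	TNL	51	LRR-RLP:2;NL:5;Other-NLR:6;TN:17;TX:38	68	119	0
At_WRR8	TNL	56	TN:12;NBS:4;NL:11;Other-NLR:2;TX:6	35	91	0
At_WRR9	NL	6	NBS:1;Other-NLR:1;TN:9;TNL:35;TX:16	62	68	0
Bju_WRR1	CNL	39	NL:10;CN:9;NBS:3	22	61	0
Bna_LepR3/Rlm2	LRR-RLP	97		0	97	0
Bna_MAPk	Other-RLK	8		0	8	0
Bna_Rlm9/4/7	Other-RLK	101		0	101	0
Bol_FocBo1	TNL	23	Other-NLR:3;TN:7;TX:14;NL:8	32	55	0
Bra_cRa/cRb	TNL	14	Other-NLR:1;TN:5;NBS:1;TX:7	14	28	0
Bra_Crr1a	TNL	28	NL:7;Other-NLR:6;TN:28;TX:19;NBS:2	62	90	0
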