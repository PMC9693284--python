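# Disease-by-gene lists for the 11 Brassicaceae diseases, as curated for
# the per-disease homolog totals. A gene may confer resistance against
# several diseases, so a homolog contributes to several disease totals but
# to exactly one gene total. Three reference genes (At_RIN4, At_Rpw8.1,
# At_Rpw8.2) appear in no disease list and contribute only to gene totals.
gene	diseases
At_ADR1	bacterial leaf spot;downy mildew;powdery mildew
At_BAK1	bacterial leaf spot;Sclerotinia stem rot
At_FLS2	bacterial leaf spot
At_NDR1	bacterial leaf spot
At_NRG1a	bacterial leaf spot;downy mildew
At_NRG1b	bacterial leaf spot;downy mildew
At_PBS1	bacterial leaf spot
At_RAC1	white rust
At_RFO1	Fusarium wilt
At_RFO2	Fusarium wilt
At_RFO3	Fusarium wilt
At_RIN4
At_RLM1a	blackleg
At_RLM1b	blackleg
At_RLM3	blackleg;grey mould;Alternaria black spot
At_RLP1	black rot
At_RLP23	Sclerotinia stem rot
At_RLP30	bacterial leaf spot;Sclerotinia stem rot
At_RLP32	bacterial leaf spot
At_RLP42	downy mildew;grey mould
At_RPM1	bacterial leaf spot
At_RPP1	downy mildew
At_RPP13	downy mildew
At_RPP2a	downy mildew
At_RPP2b	downy mildew
At_RPP39	downy mildew
At_RPP4	downy mildew
At_RPP5	downy mildew
At_RPP7	downy mildew
At_RPP8	downy mildew
At_RPS2	bacterial leaf spot
At_RPS4	bacterial leaf spot
At_RPS5	bacterial leaf spot
At_Rpw8.1
At_Rpw8.2
At_RRS1	bacterial leaf spot
At_SOBIR1	bacterial leaf spot;Sclerotinia stem rot
At_WRR12	white rust
At_WRR4a	white rust
At_WRR4b	white rust
At_WRR8	white rust
At_WRR9	white rust
Bju_WRR1	white rust
Bna_LepR3/Rlm2	blackleg
Bna_MAPk	blackleg
Bna_Rlm9/4/7	blackleg
Bol_FocBo1	Fusarium wilt
Bra_cRa/cRb	clubroot
Bra_Crr1a	clubroot
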