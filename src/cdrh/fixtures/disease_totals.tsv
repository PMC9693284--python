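# Printed per-disease homolog totals. Three of them (bacterial leaf spot,
# blackleg, clubroot) are not reproducible from the per-gene totals plus
# the disease-by-gene lists (gene sums give 795, 533 and 118); both numbers
# are reported downstream, neither is silently preferred.
disease	printed_total
Alternaria black spot	22
bacterial leaf spot	752
black rot	36
blackleg	509
clubroot	117
downy mildew	921
Fusarium wilt	283
grey mould	134
powdery mildew	45
Sclerotinia stem rot	310
white rust	544
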