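# Raw domain-label -> category lookup, matched top to bottom by
# case-insensitive substring against the label (after source-tag dispatch
# for the TM / signal-peptide / coiled-coil predictor tools). First match
# wins; anything unmatched falls into OTHER. Shipped as editable data: the
# exact evidence vocabulary per annotation tool is a best-effort
# reconstruction, not a fixed contract.
pattern	category
NB-ARC	NBS
NBS	NBS
NB_ARC	NBS
TIR	TIR
RPW8	RPW8
LYSM	LysM
LEUCINE-RICH	LRR
LEUCINE RICH	LRR
LRR	LRR
PKINASE	KINASE
PROTEIN KINASE	KINASE
KINASE	KINASE
TRANSMEMBRANE	TM
TMHELIX	TM
TMHMM	TM
SIGNAL PEPTIDE	SIGNAL_PEPTIDE
SIGNALP	SIGNAL_PEPTIDE
COILED-COIL	CC
COILED COIL	CC
COILS	CC
RX-CC	CC
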