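# Wnt signaling pathway query network (11 proteins, 17 interactions).
# Reconstructed from the canonical pathway description: Wnt1 binds the
# Frizzled/LRP receptor pair; Dishevelled is activated by Frizzled and
# inhibits the GSK-3beta/axin/APC/beta-catenin degradation complex;
# stabilized beta-catenin complexes with TCF, displacing Groucho, and the
# complex induces c-myc transcription.
WNT1	FZD1	1.0
WNT1	A2MR	1.0
FZD1	A2MR	1.0
FZD1	DVL1	1.0
DVL1	GSK3B	1.0
DVL1	AXIN1	1.0
DVL1	APC	1.0
GSK3B	AXIN1	1.0
GSK3B	APC	1.0
GSK3B	CTNNB1	1.0
AXIN1	APC	1.0
AXIN1	CTNNB1	1.0
APC	CTNNB1	1.0
CTNNB1	TCF7	1.0
TCF7	TLE1	1.0
TCF7	MYC	1.0
CTNNB1	MYC	1.0
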