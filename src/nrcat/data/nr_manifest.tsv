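symbol	trivial_name	subfamily	group	lacks_dbd
NR0B1	DAX1	NR0	NR0B	1
NR0B2	SHP	NR0	NR0B	1
NR1A1	THRa	NR1	NR1A	0
NR1A2	THRb	NR1	NR1A	0
NR1B1	RARa	NR1	NR1B	0
NR1B2	RARb	NR1	NR1B	0
NR1B3	RARg	NR1	NR1B	0
NR1C1	PPARa	NR1	NR1C	0
NR1C2	PPARd	NR1	NR1C	0
NR1C3	PPARg	NR1	NR1C	0
NR1D1	REV-ERBa	NR1	NR1D	0
NR1D2	REV-ERBb	NR1	NR1D	0
NR1F1	RORa	NR1	NR1F	0
NR1F2	RORb	NR1	NR1F	0
NR1F3	RORg	NR1	NR1F	0
NR1H2	LXRb	NR1	NR1H	0
NR1H3	LXRa	NR1	NR1H	0
NR1H4	FXR	NR1	NR1H	0
NR1I1	VDR	NR1	NR1I	0
NR1I2	PXR	NR1	NR1I	0
NR1I3	CAR	NR1	NR1I	0
NR2A1	HNF4a	NR2	NR2A	0
NR2A2	HNF4g	NR2	NR2A	0
NR2B1	RXRa	NR2	NR2B	0
NR2B2	RXRb	NR2	NR2B	0
NR2B3	RXRg	NR2	NR2B	0
NR2C1	TR2	NR2	NR2C	0
NR2C2	TR4	NR2	NR2C	0
NR2E1	TLX	NR2	NR2E	0
NR2E3	PNR	NR2	NR2E	0
NR2F1	COUP-TFI	NR2	NR2F	0
NR2F2	COUP-TFII	NR2	NR2F	0
NR2F6	EAR2	NR2	NR2F	0
NR3A1	ERa	NR3	NR3A	0
NR3A2	ERb	NR3	NR3A	0
NR3B1	ERRa	NR3	NR3B	0
NR3B2	ERRb	NR3	NR3B	0
NR3B3	ERRg	NR3	NR3B	0
NR3C1	GR	NR3	NR3C	0
NR3C2	MR	NR3	NR3C	0
NR3C3	PR	NR3	NR3C	0
NR3C4	AR	NR3	NR3C	0
NR4A1	NUR77	NR4	NR4A	0
NR4A2	NURR1	NR4	NR4A	0
NR4A3	NOR1	NR4	NR4A	0
NR5A1	SF1	NR5	NR5A	0
NR5A2	LRH1	NR5	NR5A	0
NR6A1	GCNF	NR6	NR6A	0
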