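sensillum	osn	receptors	coreceptor	glomerulus	unit_id
at1	at1A	Or67d	Orco	DA1	Or67d
at2	at2A	Or83c	Orco	DC3	Or83c
at2	at2B	Or23a	Orco	DA3	Or23a
at3	at3A	Or19a,Or19b	Orco	DC1	Or19a
at3	at3	Or2a	Orco	DA4m	Or2a
at3	at3	Or43a	Orco	DA4l	Or43a
at4	at4A	Or47b	Orco	VA1v	Or47b
at4	at4B	Or65a,Or65b,Or65c	Orco	DL3	Or65a
at4	at4C	Or88a	Orco	VA1d	Or88a
ab1	ab1A	Or42b	Orco	DM1	Or42b
ab1	ab1B	Or92a	Orco	VA2	Or92a
ab1	ab1C	Gr21a,Gr63a		V	Gr21a.Gr63a
ab1	ab1D	Or10a,Gr10a	Orco	DL1	Or10a
ab2	ab2A	Or59b	Orco	DM4	Or59b
ab2	ab2B	Or33b,Or85a	Orco	DM5	ab2B
ab2	ab2B	Or33b	Orco	DM5	Or33b
ab2	ab2B	Or85a	Orco	DM5	Or85a
ab3	ab3A	Or22a,Or22b	Orco	DM2	Or22a
ab3	ab3B	Or85b	Orco	VM5d	Or85b
ab4	ab4A	Or7a	Orco	DL5	Or7a
ab4	ab4B	Or33a,Or56a	Orco	DA2	ab4B
ab4	ab4B	Or33a	Orco	DA2	Or33a
ab4	ab4B	Or56a	Orco	DA2	Or56a
ab5	ab5A	Or82a	Orco	VA6	Or82a
ab5	ab5B	Or33b,Or47a	Orco	DM3	ab5B
ab5	ab5B	Or47a	Orco	DM3	Or47a
ab6	ab6A	Or13a	Orco	DC2	Or13a
ab6	ab6B	Or49b	Orco	VA5	Or49b
ab7	ab7A	Or98a	Orco	VM5v	Or98a
ab7	ab7B	Or67c	Orco	VC4	Or67c
ab8	ab8A	Or43b	Orco	VM2	Or43b
ab8	ab8B	Or9a	Orco	VM3	Or9a
ab9	ab9	Or67b	Orco	VA3	Or67b
ab9	ab9	Or69aA,Or69aB	Orco	D	Or69a
ab10	ab10A	Or67a	Orco	DM6	Or67a
ab10	ab10B	Or49a	Orco	DL4	Or49a
ab10	ab10B	Or85f	Orco	DL4	Or85f
ac1	ac1	Ir31a	Ir8a	VL2p	Ir31a
ac1	ac1	Ir75d	Ir25a	VL1	Ir75d
ac1	ac1	Ir92a	Ir25a,Ir76b	VM1	Ir92a
ac2	ac2	Ir75a	Ir8a	DP1l	Ir75a
ac2	ac2	Ir75d	Ir25a	VL1	Ir75d
ac2	ac2	Ir41a	Ir25a,Ir76b	VC5	Ir41a
ac3	ac3A	Ir75a,Ir75b,Ir75c	Ir8a	DL2d/v	ac3A
ac3	ac3B	Or35a	Orco,Ir76b	VC3	ac3B
ac3	ac3B	Or35a	Orco,Ir76b	VC3	Or35a
ac4	ac4	Ir84a	Ir8a	VL2a	Ir84a
ac4	ac4	Ir75d	Ir25a	VL1	Ir75d
ac4	ac4	Ir76a	Ir25a,Ir76b	VM4	Ir76a
SacIII	SacIII	Ir64a	Ir8a	DC4	Ir64a.DC4
SacIII	SacIII	Ir64a	Ir8a	DP1m	Ir64a.DP1m
pb1	pb1A	Or42a	Orco	VM7d	Or42a
pb1	pb1B	Or71a	Orco	VC2	Or71a
pb2	pb2A	Or33c,Or85e	Orco	VC1	pb2A
pb2	pb2A	Or33c	Orco	VC1	Or33c
pb2	pb2A	Or85e	Orco	VC1	Or85e
pb2	pb2B	Or46a	Orco	VA7l	Or46a
pb3	pb3A	Or59c	Orco	VM7v	Or59c
pb3	pb3B	Or85d	Orco	VA4	Or85d
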