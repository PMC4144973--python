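gene_id	annotation	digital_x	digital_y	qpcr_x	qpcr_y
GSVIVT01032968001	chalcone synthase	-5	0	-3	-1
GSVIVT01024419001	UDP-glucose flavonoid 3-O-glucosyltransferase	-13	0	ND	-1
GSVIVT01035256001	glutathione S-transferase	-8	-1	-8	-1
GSVIVT01027811001	MYB4 transcription factor	-2	1	-2	0
GSVIVT01027182001	MYBPA1 protein	7	0	4	1
GSVIVT01022659001	MYB-related transcription factor MYBA1	-5	-2	ND	-1
GSVIVT01016705001	COP1-interacting protein 7	2	0	1	0
GSVIVT01009934001	COP1-interacting protein 8	2	0	1	0
GSVIVT01030511001	E3 ubiquitin protein ligase COP1	3	0	0	-1
GSVIVT01017738001	cullin-1	3	0	7	0
GSVIVT01021502001	cullin-4	2	0	1	0
GSVIVT01015070001	RING-box protein 1a	4	0	14	0
GSVIVT01003780001	COP9 signalosome subunit 4	2	-2	1	0
GSVIVT01018273001	COP9 signalosome subunit 7	7	0	8	0
GSVIVT01009033001	cryptochrome 1	2	0	1	0
GSVIVT01028882001	anthocyanin permease 1	-7	0	-4	-1
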