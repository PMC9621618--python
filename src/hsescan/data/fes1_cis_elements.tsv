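Gene	ABRE	CGTCA-motif	TGACG-motif	TCA-element	P-box	as-1	G-box	GC-motif	Sp1	WUN-motif	ARE	ATCT-motif	box S	DRE core	GT1-motif	I-box	LTR	STRE	TCCC-motif	WRE3	CAT-box	CAAT-box	TATA-box	MYC	AAGAA-motif	MYB	GARE-motif	Box 4	3-AF1 binding site	3-AF3 binding site	dOCT	CCGTCC motif	A-box	AT-rich element	O2-site	AAAC-motif	MBS	chs-Unit 1 m1	MRE	W box	F-box	ACE	CCAAT-box	MYB recognition site	AuxRR-core	ERE	TCT-motif	GCN4_motif	CTAG-motif	LAMP-element	AE-box	CARE	JERE	TGA-element	DRE1	GATA-motif
TaFes1A-5A	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TaFes1A-5B	1	1	1	1	1	1	1	1	1	1	1	0	0	1	1	0	1	1	0	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TaFes1A-5D	1	1	1	1	0	1	1	1	1	0	1	0	1	1	1	0	1	1	0	1	0	1	1	1	0	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TaFes1B-4A	1	1	1	1	0	1	1	1	1	0	1	0	0	1	0	0	0	1	1	1	1	1	0	1	0	1	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0
TaFes1B-4B	0	1	1	1	0	1	0	1	0	1	0	0	1	1	0	0	1	1	1	1	0	1	1	1	1	1	0	1	0	0	0	1	1	0	0	0	0	0	0	1	0	1	0	0	1	1	1	1	1	0	0	0	0	0	0	0
TaFes1B-4D	1	1	1	1	0	1	1	1	1	0	0	0	1	1	0	0	1	1	1	1	0	1	1	1	1	1	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	1	0	0	1	0	0	0	1	0	0	0	0	0	0	0
TaFes1C-5A	1	1	1	1	0	1	1	1	0	1	1	1	0	0	0	1	0	1	0	1	0	1	1	1	1	1	0	0	0	0	0	1	1	0	1	0	1	0	0	0	0	1	1	1	0	0	1	0	0	1	0	0	0	0	0	0
TaFes1C-5B	1	1	1	0	1	1	1	0	1	0	0	0	1	0	0	1	0	1	1	1	1	1	1	1	1	1	0	0	0	0	0	1	1	0	0	0	1	0	0	1	0	0	0	0	1	0	1	0	0	0	1	0	0	0	0	0
TaFes1C-5D	1	1	1	1	0	1	1	0	0	0	0	0	1	1	1	1	1	1	0	0	0	1	1	1	0	1	1	0	0	0	0	1	1	0	1	0	1	0	0	1	0	0	1	1	0	1	1	0	0	0	1	1	1	1	1	1
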