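gene_a	gene_b	coefficient
ADM2	GHR	0.094222
AMHR2	OGN	0.000652
ARTN	IFI30	0.89792
CALCR	KLRK1	0.472908
CALCR	NTF3	0.110016
CCR3	IGF1	0.025693
CCR3	NCR1	0.070971
CD1A	FASLG	0.231429
CD1C	SEMA3C	-0.32233
CDK4	PIK3R1	0.489564
CHGA	PDCD1	0.483017
CTSE	MPL	0.152814
CXCL1	RELB	0.082072
CXCL5	PDCD1	0.031422
EDN1	SOS2	0.164111
EDN1	TNFRSF10D	0.299299
EPOR	PLXNA1	-0.11661
FYN	STC1	-0.37861
GHR	PLXNA2	-0.03843
GIP	OGN	0.227285
GMFB	PIK3R1	0.003817
GPR17	IL5	-0.14056
HLA-A	SPP1	-0.04005
HLA-DRB1	SPP1	-0.14776
IL15RA	SHC2	0.455341
IL18RAP	SEMA3A	-0.35545
IL1RL1	MTNR1A	-0.56454
IL5	OGN	0.361037
KIR2DS4	PRKCG	-0.49709
KITLG	SH3BP2	0.035557
KITLG	TGFBR3	0.107891
LECT2	NR6A1	-0.24611
LTB4R2	SEMA3A	-0.1266
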