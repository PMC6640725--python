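dataset_id	gene	fold_change
GSE10212	CHMP2A	1.076
GSE10212	PSMB4	-1.015
GSE10212	ACTB	1.013
GSE10212	GAPDH	1.009
GSE45487	CHMP2A	-1.025
GSE45487	PSMB4	-1.019
GSE45487	ACTB	-1.002
GSE45487	GAPDH	-1.005
GSE70662	CHMP2A	-1.151
GSE70662	PSMB4	-1.044
GSE70662	ACTB	-1.094
GSE70662	GAPDH	1.240
GSE10043	CHMP2A	1.183
GSE10043	PSMB4	1.032
GSE10043	ACTB	1.063
GSE10043	GAPDH	1.139
GSE39178	CHMP2A	1.160
GSE39178	PSMB4	1.087
GSE39178	ACTB	1.128
GSE39178	GAPDH	1.284
GSE60152	CHMP2A	-1.002
GSE60152	PSMB4	-1.087
GSE60152	ACTB	-1.015
GSE60152	GAPDH	-1.031
GSE90	PSMB4	-1.271
GSE90	ACTB	1.037
GSE90	GAPDH	1.041
GSE28546	CHMP2A	-1.141
GSE28546	PSMB4	1.072
GSE28546	ACTB	-1.207
GSE28546	GAPDH	-1.215
GSE3181	CHMP2A	-1.005
GSE3181	PSMB4	-1.071
GSE3181	ACTB	1.037
GSE3181	GAPDH	-1.011
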