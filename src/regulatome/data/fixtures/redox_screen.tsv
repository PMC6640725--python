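dataset_id	gene	fold_change
GSE10212	NOX1	3.047
GSE10212	NOX3	1.697
GSE10212	NOS2	4.370
GSE10212	GPX3	3.317
GSE70662	NOS2	-1.640
GSE70662	NOS3	-2.150
GSE70662	GPX3	1.996
GSE70662	GPX7	1.614
GSE10043	NOX1	2.194
GSE10043	NOS1	-1.824
GSE10043	NOS2	-3.747
GSE10043	MPO	9.341
GSE10043	GPX5	1.553
GSE10043	GPX7	-3.435
GSE10043	CAT	-8.137
GSE39178	NOX1	2.792
GSE39178	NOX5	2.340
GSE39178	NOS2	3.146
GSE60152	NOS3	1.988
GSE60152	GPX3	2.768
GSE60152	GPX7	1.545
GSE60152	GSR	1.854
GSE60152	SOD2	-3.878
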