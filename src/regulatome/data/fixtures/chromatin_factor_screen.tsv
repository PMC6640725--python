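dataset_id	gene	fold_change
GSE10212	GATA2	1.627
GSE70662	POLR3D	2.054
GSE70662	POLR3F	2.178
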