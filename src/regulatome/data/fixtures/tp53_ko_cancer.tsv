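#dataset_id	GSE90
#treatment	TP53 knock-out
#disease_class	cancer
#organism	Homo sapiens
#perturbed_factor	TP53
#convention	signed
gene	fold_change
TP53	-2.941
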