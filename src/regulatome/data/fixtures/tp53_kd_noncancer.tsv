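#dataset_id	GSE28546
#treatment	TP53 knock-down
#disease_class	non-cancer
#organism	Homo sapiens
#perturbed_factor	TP53
#convention	signed
gene	fold_change
TP53	-21.752
CD47	3.660
ATM	4.252
CASP1	7.056
CASP4	3.559
BCL2	3.793
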