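#dataset_id	GSE3181
#treatment	SRF knock-out
#disease_class	non-cancer
#organism	Mus musculus
#perturbed_factor	SRF
#convention	signed
gene	fold_change
SRF	-5.315
HGF	1.678
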