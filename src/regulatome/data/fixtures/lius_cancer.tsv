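#dataset_id	GSE10212
#treatment	LIUS
#disease_class	cancer
#organism	Homo sapiens
#convention	signed
gene	fold_change
BOK	1.609
CASP10	1.747
CYLD	1.599
DPP4	7.195
EZR	1.672
ATG3	3.273
ATG16L1	1.706
VAMP1	1.561
CXCL10	1.564
ANXA1	4.294
FPR1	4.701
PANX1	1.913
TP53	2.723
HK2	-1.860
CASP5	-3.734
TLR7	-5.535
MAP2K5	-3.208
CD47	-15.995
ATM	-2.035
CDC25C	-1.933
TTK	-1.713
SRC	-1.985
PDGFRA	-3.633
ITGB1	-7.891
ITGB3	-8.536
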