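#dataset_id	GSE60152
#treatment	oscillatory shear stress
#disease_class	non-cancer
#organism	Homo sapiens
#convention	signed
gene	fold_change
PMAIP1	1.913
TFRC	2.22
ENTPD1	1.568
PIK3R1	2.099
BIRC5	-2.915
CDK1	-2.364
E2F8	-1.663
DPP4	-4.136
FANCD2	-2.138
CASP1	-1.838
DDX58	-2.423
DRAM1	-1.509
ULK2	-1.561
CXCL10	-2.419
AURKA	-2.02
BUB1	-3.444
BUB1B	-2.9
CDC20	-2.144
CDC25B	-1.713
CDC25C	-1.514
CENPE	-2.47
PLK1	-2.588
TTK	-2.641
BCL2L11	-1.728
ITGB3	-2.154
TLR3	-2.346
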