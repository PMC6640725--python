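#dataset_id	GSE45487
#treatment	LIUS
#disease_class	non-cancer
#organism	Mus musculus
#convention	signed
gene	fold_change
MYC	1.519
SRF	1.528
NT5E	1.657
BAG6	1.592
NUMA1	1.866
IREB2	1.857
PTK2	1.549
PDGFRA	1.812
AKT3	2.670
BIRC5	-2.642
BIK	-2.882
CDK1	-1.806
E2F1	-2.946
E2F8	-2.603
CCND1	-1.945
GCLC	-1.513
CASP1	-1.537
CASP4	-2.122
PYCARD	-2.779
NLRP3	-2.402
IL18	-2.292
IL1B	-2.162
IFNGR1	-1.595
TLR7	-2.854
MAP2K7	-1.622
ATG10	-2.234
CD47	-1.797
ENTPD1	-3.351
TLR2	-4.067
ATM	-3.890
MYT1	-2.969
BUB1	-2.000
BUB1B	-2.395
TTK	-1.832
HGF	-2.136
KDR	-1.947
ITGA6	-2.168
TLR4	-3.319
TRADD	-1.607
BCL2	-10.126
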