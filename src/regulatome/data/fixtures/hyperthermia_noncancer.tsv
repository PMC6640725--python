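#dataset_id	GSE39178
#treatment	mild hyperthermia
#disease_class	non-cancer
#organism	Homo sapiens
#convention	signed
gene	fold_change
BAG6	8.983
E2F5	14.03
MAPK14	2.556
YWHAZ	1.901
GLS2	2.307
KRAS	6.129
MAP2K6	16.263
BECN1	6.343
ENTPD1	24.619
VAMP1	2.751
MYT1	7.391
PIK3CD	6.599
FASLG	3.046
TNFRSF25	6.836
TLR3	27.497
ATG7	1.799
MAP1LC3B2	3.834
BCL2	9.434
CASP9	-7.155
GCLC	-3.16
NLRC4	-4.517
NLRP3	-6.068
MKL2	-7.689
CD47	-7.587
P2RX7	-3.698
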