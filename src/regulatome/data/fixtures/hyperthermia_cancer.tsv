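#dataset_id	GSE10043
#treatment	mild hyperthermia
#disease_class	cancer
#organism	Homo sapiens
#convention	signed
gene	fold_change
BAG3	21.791
PMAIP1	1.95
CASP7	1.607
CDKN1A	3.834
E2F5	1.999
SLC25A4	2.011
CYLD	1.708
HSPB1	4.717
CASP1	2.183
IL1B	1.919
EZR	2.265
MPO	9.341
VAMP1	4.001
SNAP25	1.797
NT5E	8.598
ANXA1	1.655
FPR1	9.078
CDC25A	1.534
BUB1	2.325
PLK2	10.193
AURKC	2.783
EGFR	1.77
ITGB1	10.408
ITGB3	3.54
FAS	2.16
ATG5	3.488
TP53	2.79
CAD	-1.729
TFRC	-1.747
NLRP1	-3.732
IFNGR1	-1.948
TLR7	-5.953
MKL2	-1.704
KRAS	-1.742
MAP2K7	-3.807
MTOR	-1.616
ENTPD1	-3.162
CCNE1	-1.91
BUB1B	-1.741
SRC	-1.916
HGF	-8.403
BCL2	-1.536
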