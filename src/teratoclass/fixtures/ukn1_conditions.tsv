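compound_id	bucket	concentration_label	truth	cytotoxic	up	down
AMP	1x	1x	non_teratogen	False	0	0
AMP	20x	20x	non_teratogen	False	0	0
ASC	1x	1x	non_teratogen	False	0	0
ASC	20x	20x	non_teratogen	False	0	0
BSP	1x	1x	non_teratogen	False	0	0
BSP	20x	20x	non_teratogen	False	0	0
CPA	1x	1x	non_teratogen	False	0	0
CPA	20x	20x	non_teratogen	False	0	0
DEX	1x	1x	non_teratogen	False	0	0
DEX	20x	20x	non_teratogen	False	0	0
DPH	1x	1x	non_teratogen	False	0	0
DPH	20x	20x	non_teratogen	False	0	0
DOA	1x	1x	non_teratogen	False	0	0
DOA	20x	20x	non_teratogen	False	0	0
FAM	1x	1x	non_teratogen	False	0	0
FAM	20x	20x	non_teratogen	False	0	0
FOA	1x	1x	non_teratogen	False	0	0
FOA	20x	20x	non_teratogen	False	0	0
LEV	1x	1x	non_teratogen	False	18	20
LEV	20x	20x	non_teratogen	False	0	0
LIO	1x	1x	non_teratogen	False	0	0
LIO	20x	20x	non_teratogen	False	27	57
MAG	1x	1x	non_teratogen	False	0	0
MAG	20x	20x	non_teratogen	False	13	3
MET	1x	1x	non_teratogen	False	0	0
MET	20x	20x	non_teratogen	False	0	2
RAN	1x	1x	non_teratogen	False	0	0
RAN	20x	20x	non_teratogen	False	0	0
RET	1x	1x	non_teratogen	False	0	0
SUC	1x	1x	non_teratogen	False	0	0
SUC	20x	20x	non_teratogen	False	0	0
9RA	1x	1x	teratogen	False	1956	1785
9RA	20x	20x	teratogen	False	2426	1887
ACI	1x	1x	teratogen	False	1803	1604
ACI	20x	20x	teratogen	False	2309	1795
ACD	1x	1x	teratogen	True	NA	NA
ACD	20x	20x	teratogen	True	NA	NA
ATO	1x	1x	teratogen	True	NA	NA
ATO	20x	20x	teratogen	True	NA	NA
CMZ	1x	1x	teratogen	False	0	0
CMZ	20x	10x	teratogen	False	910	591
DXR	1x	1x	teratogen	True	NA	NA
DXR	20x	20x	teratogen	True	NA	NA
ENT	1x	1x	teratogen	False	48	30
ENT	20x	20x	teratogen	True	NA	NA
FPV	1x	1x	teratogen	False	0	0
FPV	20x	20x	teratogen	False	1551	1290
ISO	1x	1x	teratogen	False	1029	703
ISO	20x	20x	teratogen	True	NA	NA
LFL	1x	1x	teratogen	False	614	415
LTH	1x	1x	teratogen	False	0	0
LTH	20x	20x	teratogen	True	NA	NA
MTX	1x	1x	teratogen	False	435	209
MTX	20x	20x	teratogen	False	687	622
MEM	1x	1x	teratogen	False	0	0
MEM	20x	20x	teratogen	False	0	0
PAN	1x	1x	teratogen	True	NA	NA
PAN	20x	20x	teratogen	True	NA	NA
PAX	1x	1x	teratogen	False	0	0
PAX	20x	20x	teratogen	True	NA	NA
PHE	1x	1x	teratogen	False	0	0
RET	20x	20x	teratogen	False	1032	936
TER	1x	1x	teratogen	False	1829	1394
THD	1x	1x	teratogen	False	41	21
THD	20x	20x	teratogen	False	0	0
TSA	1x	1x	teratogen	False	4	0
TSA	20x	20x	teratogen	True	NA	NA
VPA	1x	1x	teratogen	False	630	364
VPA	20x	1.67x	teratogen	False	878	685
VIN	1x	1x	teratogen	True	NA	NA
VIN	20x	20x	teratogen	True	NA	NA
VIS	1x	1x	teratogen	False	0	0
VST	1x	1x	teratogen	True	NA	NA
VST	20x	20x	teratogen	True	NA	NA
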