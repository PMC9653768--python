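compound_id	truth	sps_ukn1_20x	sps_ukk2_1x	sps_mean_20x	top1000_ukn1_20x	top1000_ukk2_1x	top1000_mean_20x	qpcr_sps_ukn1_20x	qpcr_top1000_ukn1_20x
AMP	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
ASC	non_teratogen	TN	TN	TN	FP	TN	TN	TN	FP
BSP	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
CPA	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
DEX	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
DPH	non_teratogen	TN	TN	TN	FP	FP	FP	TN	TN
DOA	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
FAM	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
FOA	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
LEV	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
LIO	non_teratogen	TN	TN	TN	TN	TN	TN	TN	FP
MAG	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
MET	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
RAN	non_teratogen	TN	TN	TN	TN	TN	TN	TN	TN
RET	non_teratogen	NA	TN	NA	NA	TN	NA	NA	NA
SUC	non_teratogen	TN	TN	TN	FP	FP	FP	TN	TN
9RA	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
ACI	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
ACD	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
ATO	teratogen	TP	FN	TP	TP	FN	TP	TP	TP
CMZ	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
DXR	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
ENT	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
FPV	teratogen	TP	FN	TP	TP	TP	TP	TP	TP
ISO	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
LFL	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
LTH	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
MTX	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
MEM	teratogen	FN	TP	FN	TP	TP	TP	FN	FN
PAN	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
PAX	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
PHE	teratogen	FN	FN	FN	TP	TP	TP	FN	FN
RET	teratogen	TP	NA	TP	TP	NA	TP	TP	TP
TER	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
THD	teratogen	FN	TP	TP	FN	TP	TP	FN	TP
TSA	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
VPA	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
VIN	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
VIS	teratogen	FN	FN	FN	FN	TP	TP	FN	FN
VST	teratogen	TP	TP	TP	TP	TP	TP	TP	TP
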