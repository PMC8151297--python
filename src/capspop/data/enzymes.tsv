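name	motif	cut_offset	outside_cutter
ApoI	RAATTY	1	0
BbsI	GAAGAC	8	1
BccI	CCATC	9	1
BsaBI	GATNNNNATC	5	0
BsmI	GAATGC	7	1
BsrDI	GCAATG	8	1
BssSI	CACGAG	1	0
BstAPI	GCANNNNTGC	7	0
BstBI	TTCGAA	2	0
BstNI	CCWGG	2	0
BtsCI	GGATG	7	1
BtsI	GCAGTG	8	1
DpnI	GATC	2	0
Fnu4HI	GCNGC	2	0
HaeIII	GGCC	2	0
HinfI	GANTC	1	0
HphI	GGTGA	13	1
Hpy166II	GTNNAC	3	0
Hpy188I	TCNGA	3	0
Hpy99I	CGWCG	5	0
HpyAV	CCTTC	11	1
HpyCH4III	ACNGT	3	0
HpyCH4IV	ACGT	1	0
HpyCH4V	TGCA	2	0
MluCI	AATT	0	0
MnlI	CCTC	11	1
MseI	TTAA	1	0
MspI	CCGG	1	0
NcoI	CCATGG	1	0
NdeI	CATATG	2	0
NlaIV	GGNNCC	3	0
PvuI	CGATCG	4	0
RsaI	GTAC	2	0
SfaNI	GCATC	10	1
TaqI	TCGA	1	0
TaqI-v2	TCGA	1	0
Tsp45I	GTSAC	0	0
XcmI	CCANNNNNNNNNTGG	8	0
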