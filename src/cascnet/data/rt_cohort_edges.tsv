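# Published ROI-wise directed causal edge list (post-radiotherapy NPC cohort).
# Columns: source, target, signed path coefficient (gc), signed z value.
source	target	gc	z
TPOmid.L	ITG.L	-1.76	-10.50
PHG.R	TPOmid.L	-1.54	-9.23
REC.R	TPOmid.L	1.63	9.44
CAU.L	TPOmid.L	-0.75	-4.58
CAU.R	TPOmid.L	-0.60	-3.68
PUT.L	TPOmid.L	-0.78	-4.73
CC1.R	TPOmid.L	1.01	5.81
PCUN.L	TPOmid.L	0.79	4.50
PHG.R	ITG.L	-4.39	-26.03
PHG.R	PCUN.L	-0.67	-4.06
PHG.R	CC1.R	-0.55	-3.35
PHG.R	PUT.L	-0.45	-2.78
PHG.L	ITG.L	-5.06	-29.97
PHG.L	PCUN.L	0.83	4.76
REC.R	PCUN.L	1.75	10.19
REC.R	CC1.R	0.51	2.87
CAU.L	PHG.L	-0.40	-2.49
CAU.R	ITG.L	-0.84	-5.06
CAU.R	CC1.R	-0.50	-3.10
CAU.R	PCUN.L	-0.45	-2.78
CAU.R	PHG.R	0.43	2.37
PUT.L	ITG.L	-1.90	-11.33
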