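label	HM067837	MT-2014	JZ-2021	CN	TL	QY
HM067837	0	0.202	0.187	0.058	0.058	0.140
MT-2014	0.202	0	0.210	0.209	0.209	0.211
JZ-2021	0.187	0.210	0	0.183	0.183	0.190
CN	0.058	0.209	0.183	0	0.001	0.148
TL	0.058	0.209	0.183	0.001	0	0.149
QY	0.140	0.211	0.190	0.148	0.149	0
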