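label	accession	morphospecies
HM067837	HM067837	Vietnamella sinensis
MT-2014	KM244655	Vietnamella sp. MT-2014
JZ-2021	MF352146	Vietnamella sp. JZ-2021
CN	OK265111	Vietnamella sinensis
TL	OK265109	Vietnamella sinensis
QY	OK265110	Vietnamella sinensis
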