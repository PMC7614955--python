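lineage	ALPHA_BETA	BETA_ALPHA_I	BETA_ALPHA_II
Chromerida	1	1	1
Gregarinia	1	0	1
Marosporida	1	0	1
Cryptosporidia	0	1	0
Nephromycida	0	0	1
Sarcocystidae	0	1	1
Eimeriidae	0	1	0
Haemosporida	0	1	0
Piroplasmida	0	0	0
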