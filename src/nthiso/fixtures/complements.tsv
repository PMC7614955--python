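lineage	gene_id	isoform	paralog_group
Chromerida	chromera_nth_ab	ALPHA_BETA	NA
Chromerida	vitrella_nth_ba1	BETA_ALPHA	GROUP_I
Chromerida	chromera_nth_ba2	BETA_ALPHA	GROUP_II
Gregarinia	gregarine_nth_ab	ALPHA_BETA	NA
Gregarinia	porospora_nth_ab_t1	ALPHA_BETA	NA
Gregarinia	porospora_nth_ab_t2	ALPHA_BETA	NA
Gregarinia	porospora_nth_ab_t3	ALPHA_BETA	NA
Gregarinia	porospora_nth_ba2_t1	BETA_ALPHA	GROUP_II
Gregarinia	porospora_nth_ba2_t2	BETA_ALPHA	GROUP_II
Marosporida	rhytidocystis_nth_ab1	ALPHA_BETA	NA
Marosporida	rhytidocystis_nth_ab2	ALPHA_BETA	NA
Marosporida	rhytidocystis_nth_ba2_1	BETA_ALPHA	GROUP_II
Marosporida	rhytidocystis_nth_ba2_2	BETA_ALPHA	GROUP_II
Cryptosporidia	cryptosporidium_nth1	BETA_ALPHA	GROUP_I
Cryptosporidia	cryptosporidium_nth2	BETA_ALPHA	GROUP_I
Nephromycida	cardiosporidium_nth_ba2_1	BETA_ALPHA	GROUP_II
Nephromycida	cardiosporidium_nth_ba2_2	BETA_ALPHA	GROUP_II
Nephromycida	nephromyces_nth_ba2_1	BETA_ALPHA	GROUP_II
Nephromycida	nephromyces_nth_ba2_2	BETA_ALPHA	GROUP_II
Nephromycida	nephromyces_nth_ba2_3	BETA_ALPHA	GROUP_II
Sarcocystidae	toxoplasma_nth_ba1	BETA_ALPHA	GROUP_I
Sarcocystidae	toxoplasma_nth_ba2	BETA_ALPHA	GROUP_II
Eimeriidae	eimeria_nth_ba1	BETA_ALPHA	GROUP_I
Haemosporida	plasmodium_nth_ba1	BETA_ALPHA	GROUP_I
Haemosporida	haemoproteus_nth_ba1	BETA_ALPHA	GROUP_I
Haemosporida	leucocytozoon_nth_ba1	BETA_ALPHA	GROUP_I
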