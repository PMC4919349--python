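strain_name	study_section	SE	LAS	CAS	ERG11	ERG24	ERG25	ERG26	ERG27	ERG4_DHCR24
Corallococcus coralloides	this_study	COCOR_01775	.	COCOR_01777	COCOR_02429	.	.	.	.	COCOR_02182
Cystobacter fuscus	this_study	D187_003106	.	D187_003104	D187_005870	.	D187_005391	.	.	D187_001522
Enhygromyxa salina	this_study	Ga0055550_102654	Ga0055550_114516	.	Ga0055550_103211	Ga0055550_105926	Ga0055550_101078	.	.	Ga0055550_101115
Eudoraea adriatica	this_study	G504DRAF_2315	G504DRAFT_2316	.	.	.	.	.	.	.
Fluviicola taffensis	this_study	Fluta_3221	.	Fluta_3214	.	.	.	.	.	.
Methylobacter luteus	this_study	MetluDRAFT_1256	MetluDRAFT_1255	.	MetluDRAFT_1253	.	.	.	.	MetluDRAFT_1263
Methylobacter whittenburyi	this_study	GY38DRAFT_3868	GY38DRAFT_3867	.	GY38DRAFT_3865	.	.	.	.	GY38DRAFT_3875
Methyloceanibacter caenitepidi	this_study	GL4_3111	.	GL4_3110	.	.	.	.	.	.
Methylococcus capsulatus Texas	this_study	H156DRAF_2531	H156DRAFT_2530	.	H156DRAFT_1746	.	.	.	.	H156DRAF_0889
Methylosarcina lacus	this_study	MetlaDRAFT_0846	MetlaDRAFT_0845	.	MetlaDRAFT_0843	.	.	.	.	.
Plesiocystis pacifica	this_study	PPSIR1_02838	PPSIR1_02843	.	PPSIR1_36894	PPSIR1_23244	PPSIR1_14275	PPSIR1_17435	.	.
Sandaracinus amylolyticus	this_study	Ga0055546_12562	Ga0055546_18051	.	Ga0055546_101121	Ga0055546_17127	Ga0055546_103226	Ga0055546_17162	.	Ga0055546_16346
Nannocystis exedens	previous_study	Ga0008035_04851	Ga0008035_04852	.	Ga0008035_02418	Ga0008035_01127	Ga0008035_06338	Ga0008035_00875	.	Ga0008035_06674
Stigmatella aurantiaca	previous_study	STAUR_5420	.	STAUR_5418	STAUR_2030	.	STAUR_2074	.	.	.
Gemmata obscuriglobus	previous_study	GobsU_010100006610	GobsU_010100006605	.	.	.	.	.	.	.
Methylococcus capsulatus Bath	previous_study	MCA2872	MCA2873	.	MCA2711	.	.	.	.	MCA1404
Methylomicrobium alcaliphilum 20Z	previous_study	MEALZ_0767	MEALZ_0768	.	MEALZ_0770	MEALZ_1312	.	.	.	MEALZ_3890
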