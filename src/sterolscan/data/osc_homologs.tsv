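strain_name	locus_tag	taxon_group	phylum	environment
Corallococcus coralloides DSM 2259	COCOR_01777	Myxobacteria	Proteobacteria	Soil, Canada
Cystobacter fuscus DSM 2262	D187_003104	Myxobacteria	Proteobacteria	Soil, Canada
Enhygromyxa salina DSM 15201	Ga0055550_114516	Myxobacteria	Proteobacteria	Marine, intertidal zone
Labilithrix luteola DSM 27648	AKJ09_09404	Myxobacteria	Proteobacteria	Soil, Yakushima Island
Nannocystis exedens ATCC 25963	Ga0008035_02275	Myxobacteria	Proteobacteria	Soil, Desert
Plesiocystis pacifica SIR-1	PPSIR1_04883	Myxobacteria	Proteobacteria	Marine, intertidal zone
Sandaracinus amylolyticus DSM 53668	Ga0055546_18051	Myxobacteria	Proteobacteria	Soil, India
Stigmatella aurantiaca DW4/3-1	STAUR_5418	Myxobacteria	Proteobacteria	Soil
Methylobacter luteus IMV-B-3098	MetluDRAFT_1255	Methylococcales	Proteobacteria	Sewage
Methylobacter sp. BBA5.1	EK22DRAFT_03359	Methylococcales	Proteobacteria	Environmental, JGI
Methylobacter whittenburyi ACM 3310	GY38DRAFT_3867	Methylococcales	Proteobacteria	Terrestrial
Methylobacterium marinus A45	MetmaDRAFT_3943	Methylococcales	Proteobacteria	Marine water column, Framvaren Fjord, Norway
Methylocaldum sp. 175	JC06DRAFT_3873	Methylococcales	Proteobacteria	Environmental, JGI
Methylocaldum szegediense O-12	MetszDRAFT_3769	Methylococcales	Proteobacteria	Hot spring
Methylococaceae sp. 73a	EK23DRAFT_02566	Methylococcales	Proteobacteria	Environmental, JGI
Methylococcus capsulatus Bath	MCA2873	Methylococcales	Proteobacteria	Hot spring
Methylococcus capsulatus Texas	H156DRAFT_2530	Methylococcales	Proteobacteria	Sewer sludge
Methylomicrobium alcaliphilum 20Z	MEALZ_0768	Methylococcales	Proteobacteria	Sediment, Tuva soda lakes
Methylomicrobium buryatense 5G	METBUDRAFT_4052	Methylococcales	Proteobacteria	Sediment, Transbaikal soda lakes
Methylomicrobium kenyense AMO1	IQ34DRAFT_3157	Methylococcales	Proteobacteria	Surface sediment Kenyan soda lake
Methylosarcina lacus LW14	MetlaDRAFT_0845	Methylococcales	Proteobacteria	Sediment, Lake Washington
Methyloceanibacter caenitepidi str. Gela4	Ga0077927_11952	Rhizobiales	Proteobacteria	Marine sediment hydrothermal vent
Eudoraea adriatica DSM 19308	G504DRAFT_2316	Bacteroidetes	Bacteroidetes	Coastal waters, Adriatic Sea
Eudoraea sp. SCGC 5358	K485DRAFT_00205	Bacteroidetes	Bacteroidetes	Marine, North Sea, JGI
Eudoraea sp. SCGC 5441	K506DRAFT_00376	Bacteroidetes	Bacteroidetes	Marine, North Sea, JGI
Eudoraea sp. SCGC 5444	K507DRAFT_00676	Bacteroidetes	Bacteroidetes	Marine, North Sea, JGI
Fluviicola taffensis RW262 DSM 16823	Fluta_3214	Bacteroidetes	Bacteroidetes	Freshwater, River Taff
Planktothrix sp. st147	st147_cleanDRAFT_00043800	Cyanobacteria	Cyanobacteria	Freshwater, Lake Langersee
Prochloron didemni P2-Fiji	Ga0040003_100917	Cyanobacteria	Cyanobacteria	Tunicate symbiont (Lissoclinum patella)
Prochloron didemni P3-Solomon	Ga0040004_00276	Cyanobacteria	Cyanobacteria	Tunicate symbiont (Lissoclinum patella)
Prochloron didemni P4-Papua New Guinea	Ga0040005_03818	Cyanobacteria	Cyanobacteria	Tunicate symbiont (Lissoclinum patella)
Westiella intricata UH HT-29-1	HT291_04925	Cyanobacteria	Cyanobacteria	Soil, Moen Island
Gemmata obscuriglobus UQM 2246	GobsU_010100006605	Planctomycetes	Planctomycetes	Freshwater dam, Queensland, Australia
Gemmata sp. IIL30	Ga0036985_07173	Planctomycetes	Planctomycetes	Environmental, JGI
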