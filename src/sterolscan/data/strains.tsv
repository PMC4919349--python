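strain_name	taxon_group	phylum	growth_conditions	source
Corallococcus coralloides	Myxobacteria	Proteobacteria	DSMZ medium 222 at 30C, liquid, stationary phase	DSMZ
Cystobacter fuscus	Myxobacteria	Proteobacteria	DSMZ medium 222 at 30C, liquid, stationary phase	DSMZ
Enhygromyxa salina	Myxobacteria	Proteobacteria	DSMZ medium 958 on agar plates at 30C	DSMZ
Fluviicola taffensis	Bacteroidetes	Bacteroidetes	DSMZ medium 1 liquid at 30C	DSMZ
Methylobacter luteus	Methylococcales	Proteobacteria	NMS medium plus methane at 30C	M.G. Kalyuzhnaya
Methylobacter whittenburyi	Methylococcales	Proteobacteria	NMS medium plus methane at 30C	M.G. Kalyuzhnaya
Methyloceanibacter caenitepidi	Rhizobiales	Proteobacteria	DSMZ medium 1488 plus 1% methanol at 37C	M.G. Kalyuzhnaya
Methylococcus capsulatus Texas	Methylococcales	Proteobacteria	NMS medium plus methane at 30C	ATCC
Methylosarcina lacus	Methylococcales	Proteobacteria	NMS medium plus methane at 30C	M.G. Kalyuzhnaya
Plesiocystis pacifica	Myxobacteria	Proteobacteria	DSMZ medium 958 on agar plates at 30C	DSMZ
Sandaracinus amylolyticus	Myxobacteria	Proteobacteria	DSMZ medium 67 on agar plates at 30C	DSMZ
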