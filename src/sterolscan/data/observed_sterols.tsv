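strain_name	study_section	taxon_group	squalene	cycloartenol	lanosterol	parkeol	4,4-dimethylcholesta-8,24-dien-3-ol	4,4-dimethylcholesta-8-en-3-ol	4-methylcholesta-8,24-dien-3-ol	4-methylcholesta-8-en-3-ol	zymosterol
Corallococcus coralloides	this_study	Myxobacteria	+								
Cystobacter fuscus	this_study	Myxobacteria	+	+							
Enhygromyxa salina	this_study	Myxobacteria		+	+						+
Plesiocystis pacifica	this_study	Myxobacteria		+	+						+
Sandaracinus amylolyticus	this_study	Myxobacteria			+						+
Methylobacter luteus	this_study	Methylococcales						+		+	
Methylobacter whittenburyi	this_study	Methylococcales					+	+	+	+	
Methylococcus capsulatus Texas	this_study	Methylococcales					+	+	+	+	
Methylosarcina lacus	this_study	Methylococcales					+		+		
Fluviicola taffensis	this_study	Bacteroidetes		+							
Methyloceanibacter caenitepidi	this_study	Rhizobiales		+							
Nannocystis exedens	previous_study	Myxobacteria	+		+		+	+	+	+	+
Stigmatella aurantiaca	previous_study	Myxobacteria	+	+							
Cystobacter sp.	previous_study	Myxobacteria	+	+	+						
Corallococcus sp.	previous_study	Myxobacteria	+								
Gemmata obscuriglobus	previous_study	Planctomycetes			+	+					
Methylococcus capsulatus Bath	previous_study	Methylococcales					+	+	+	+	
Methylomicrobium alcaliphilum 20Z	previous_study	Methylococcales						+			
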