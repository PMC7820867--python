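taxon_id	phylum	class	order	family	genus
OTU_1	Bacteroidetes	Bacteroidia	Bacteroidales	Bacteroidaceae	Bacteroides
OTU_2	Bacteroidetes	Bacteroidia	Bacteroidales	Prevotellaceae	Prevotella
OTU_3	Proteobacteria	Gammaproteobacteria	Enterobacterales	Enterobacteriaceae	Escherichia/Shigella
OTU_4	Firmicutes	Clostridia	Eubacteriales	Ruminococcaceae	Faecalibacterium
OTU_5	Firmicutes	Clostridia	Eubacteriales	Lachnospiraceae	unclassified
OTU_6	Firmicutes	Clostridia	Eubacteriales	Ruminococcaceae	Ruminococcus
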