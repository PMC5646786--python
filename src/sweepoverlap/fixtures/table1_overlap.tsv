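species	comparison	source	symbol_raw	gene_class
horse	amh_domesticate_overlap	table1	AMBRA1	protein_coding
cat	amh_domesticate_overlap	table1	BRAF	protein_coding
horse	amh_domesticate_overlap	table1	BRAF	protein_coding
horse	amh_domesticate_overlap	table1	CACNA1D	protein_coding
dog	amh_domesticate_overlap	table1	COA5	protein_coding
dog	amh_domesticate_overlap	table1	COL11A1	protein_coding
dog	amh_domesticate_overlap	table1	COQ10B	protein_coding
horse	amh_domesticate_overlap	table1	DLGAP1	protein_coding
cattle	amh_domesticate_overlap	table1	ERBB4	protein_coding
cattle	amh_domesticate_overlap	table1	FAM172A	protein_coding
dog	amh_domesticate_overlap	table1	FAM172A	protein_coding
dog	amh_domesticate_overlap	table1	GGT7	protein_coding
cat	amh_domesticate_overlap	table1	GRIA1	protein_coding
dog	amh_domesticate_overlap	table1	GRIK3	protein_coding
cattle	amh_domesticate_overlap	table1	GRIK3	protein_coding
cat	amh_domesticate_overlap	table1	HSD3B7	protein_coding
dog	amh_domesticate_overlap	table1	HSPD1	protein_coding
dog	amh_domesticate_overlap	table1	HSPE1	protein_coding
cat	amh_domesticate_overlap	table1	ITGA9	protein_coding
cattle	amh_domesticate_overlap	table1	LRP1B	protein_coding
dog	amh_domesticate_overlap	table1	LYST	protein_coding
dog	amh_domesticate_overlap	table1	MOB4	protein_coding
cat	amh_domesticate_overlap	table1	MYLK3	protein_coding
dog	amh_domesticate_overlap	table1	NCOA6	protein_coding
cat	amh_domesticate_overlap	table1	NEK4	protein_coding
horse	amh_domesticate_overlap	table1	NT5DC2	protein_coding
horse	amh_domesticate_overlap	table1	NTM	protein_coding
cat	amh_domesticate_overlap	table1	PLAC8L1	protein_coding
cattle	amh_domesticate_overlap	table1	PLAC8L1	protein_coding
cat	amh_domesticate_overlap	table1	PPAP2A	protein_coding
cat	amh_domesticate_overlap	table1	PPAPDC1B	protein_coding
cat	amh_domesticate_overlap	table1	PRR11	protein_coding
cattle	amh_domesticate_overlap	table1	PVRL3	protein_coding
dog	amh_domesticate_overlap	table1	RFTN2	protein_coding
cat	amh_domesticate_overlap	table1	RNPC3	protein_coding
dog	amh_domesticate_overlap	table1	RNPC3	protein_coding
dog	amh_domesticate_overlap	table1	SF3B1	protein_coding
dog	amh_domesticate_overlap	table1	SKA2	protein_coding
cattle	amh_domesticate_overlap	table1	SNRPD1	protein_coding
horse	amh_domesticate_overlap	table1	STAB1	protein_coding
cat	amh_domesticate_overlap	table1	SYTL1	protein_coding
cattle	amh_domesticate_overlap	table1	TAS2R16	protein_coding
cat	amh_domesticate_overlap	table1	TEX14	protein_coding
cat	amh_domesticate_overlap	table1	TP53BP1	protein_coding
cat	amh_domesticate_overlap	table1	ZMYND10	protein_coding
cattle	amh_domesticate_overlap	table1	ZNF521	protein_coding
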