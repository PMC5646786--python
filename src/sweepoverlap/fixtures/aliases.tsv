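# Legacy -> current HGNC symbol renames seen in older sweep-screen tables.
raw	canonical
PPAP2A	PLPP1
PPAP2B	PLPP3
PPAPDC1B	PLPP5
PVRL3	NECTIN3
PVRL1	NECTIN1
HER4	ERBB4
MKL1	MRTFA
C2ORF47	MAIP1
FAM175A	ABRAXAS1
KIAA0101	PCLAF
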