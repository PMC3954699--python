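# sitescan bundled site definitions: 20 reference functional families.
# Columns: name, pattern, conserved_index, residue_name, functional_atom.
# The pattern column is intentionally empty: PROSITE pattern strings are
# database content supplied by the user at build time. conserved_index is the
# 1-based index of the conserved position within the pattern.
# Note: the PA2_HIS row is shipped as published upstream although HIS has no
# SG atom (flagged by sitescan.site_examples.validate_site_table; NE2 is the
# plausible intent).
name	pattern	conserved_index	residue_name	functional_atom
ADH_SHORT		5	TYR	OH
ALPHA_CA_1		11	HIS	NE2
ASP_PROTEASE		4	ASP	OD2
ATPASE_ALPHA_BETA		8	SER	OG
CARBOXYLESTERASE_B_1		3	CYS	SG
CYTOCHROME_P450		8	CYS	SG
EF_HAND		1	ASP	OD1
EGF_1		10	CYS	SG
IG_MHC		3	CYS	SG
INSULIN		2	CYS	SG
LACTALBUMIN_LYSOZYME		3	CYS	SG
LECTIN_LEGUME_BETA		6	ASP	OD1
PA2_HIS		2	HIS	SG
PROTEIN_KINASE_ST		5	ASP	OD2
PROTEIN_KINASE_TYR		5	ASP	OD2
RNASE_PANCREATIC		2	LYS	NZ
SOD_CU_ZN_1		3	HIS	NE2
TRYPSIN_HIS		5	HIS	NE2
TRYPSIN_SER		6	SER	OG
ZINC_PROTEASE		5	GLU	OE1
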