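# sitescan property catalog
# catalog_version: 1
# 80 properties per shell: AtomName(6) + ChemicalGroup(6) + AtomProperties(30)
#   + ResidueName(22) + ResidueProperties(6) + SecondaryStructure(10).
# The five scalar atom properties are element-typed (C/N/O/S/OTHER/ANY buckets):
#   5 scalars x 6 buckets = 30 slots.
group	name	rule	params
AtomName	C	atom_element	C
AtomName	N	atom_element	N
AtomName	O	atom_element	O
AtomName	S	atom_element	S
AtomName	ANY	atom_any	
AtomName	OTHER	atom_element	OTHER
ChemicalGroup	Hydroxyl	chemical_group	Hydroxyl
ChemicalGroup	Amide	chemical_group	Amide
ChemicalGroup	Amine	chemical_group	Amine
ChemicalGroup	Carbonyl	chemical_group	Carbonyl
ChemicalGroup	RingSystem	chemical_group	RingSystem
ChemicalGroup	Peptide	chemical_group	Peptide
AtomProperties	VDWVolume_C	scalar	VDWVolume,C
AtomProperties	VDWVolume_N	scalar	VDWVolume,N
AtomProperties	VDWVolume_O	scalar	VDWVolume,O
AtomProperties	VDWVolume_S	scalar	VDWVolume,S
AtomProperties	VDWVolume_OTHER	scalar	VDWVolume,OTHER
AtomProperties	VDWVolume_ANY	scalar	VDWVolume,ANY
AtomProperties	Charge_C	scalar	Charge,C
AtomProperties	Charge_N	scalar	Charge,N
AtomProperties	Charge_O	scalar	Charge,O
AtomProperties	Charge_S	scalar	Charge,S
AtomProperties	Charge_OTHER	scalar	Charge,OTHER
AtomProperties	Charge_ANY	scalar	Charge,ANY
AtomProperties	Hydrophobicity_C	scalar	Hydrophobicity,C
AtomProperties	Hydrophobicity_N	scalar	Hydrophobicity,N
AtomProperties	Hydrophobicity_O	scalar	Hydrophobicity,O
AtomProperties	Hydrophobicity_S	scalar	Hydrophobicity,S
AtomProperties	Hydrophobicity_OTHER	scalar	Hydrophobicity,OTHER
AtomProperties	Hydrophobicity_ANY	scalar	Hydrophobicity,ANY
AtomProperties	Mobility_C	scalar	Mobility,C
AtomProperties	Mobility_N	scalar	Mobility,N
AtomProperties	Mobility_O	scalar	Mobility,O
AtomProperties	Mobility_S	scalar	Mobility,S
AtomProperties	Mobility_OTHER	scalar	Mobility,OTHER
AtomProperties	Mobility_ANY	scalar	Mobility,ANY
AtomProperties	SolventAccessibility_C	scalar	SolventAccessibility,C
AtomProperties	SolventAccessibility_N	scalar	SolventAccessibility,N
AtomProperties	SolventAccessibility_O	scalar	SolventAccessibility,O
AtomProperties	SolventAccessibility_S	scalar	SolventAccessibility,S
AtomProperties	SolventAccessibility_OTHER	scalar	SolventAccessibility,OTHER
AtomProperties	SolventAccessibility_ANY	scalar	SolventAccessibility,ANY
ResidueName	ALA	residue_name	ALA
ResidueName	ARG	residue_name	ARG
ResidueName	ASN	residue_name	ASN
ResidueName	ASP	residue_name	ASP
ResidueName	CYS	residue_name	CYS
ResidueName	GLN	residue_name	GLN
ResidueName	GLU	residue_name	GLU
ResidueName	GLY	residue_name	GLY
ResidueName	HIS	residue_name	HIS
ResidueName	ILE	residue_name	ILE
ResidueName	LEU	residue_name	LEU
ResidueName	THR	residue_name	THR
ResidueName	LYS	residue_name	LYS
ResidueName	MET	residue_name	MET
ResidueName	PHE	residue_name	PHE
ResidueName	PRO	residue_name	PRO
ResidueName	SER	residue_name	SER
ResidueName	TRP	residue_name	TRP
ResidueName	TYR	residue_name	TYR
ResidueName	VAL	residue_name	VAL
ResidueName	HOH	residue_name	HOH
ResidueName	OTHER	residue_name	OTHER
ResidueProperties	Hydrophobic	residue_class	Hydrophobic
ResidueProperties	Charged	residue_class	Charged
ResidueProperties	Polar	residue_class	Polar
ResidueProperties	NonPolar	residue_class	NonPolar
ResidueProperties	Basic	residue_class	Basic
ResidueProperties	Acidic	residue_class	Acidic
SecondaryStructure	3Helix	ss	3Helix
SecondaryStructure	4Helix	ss	4Helix
SecondaryStructure	5Helix	ss	5Helix
SecondaryStructure	Bridge	ss	Bridge
SecondaryStructure	Strand	ss	Strand
SecondaryStructure	Turn	ss	Turn
SecondaryStructure	Bend	ss	Bend
SecondaryStructure	Coil	ss	Coil
SecondaryStructure	Het	ss	Het
SecondaryStructure	Unknown	ss	Unknown
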