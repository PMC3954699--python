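# sitescan bundled site -> sequence-domain mapping used to score a
# sequence-level domain annotator against site-level truth. A site is
# scorable only if it maps to at least one domain; ZINC_PROTEASE has no
# mapping and is unscorable by design.
# Columns: site, domains (comma-separated).
site	domains
ADH_SHORT	ADH_SHORT,NAD dependent epimerase/dehydratase
ALPHA_CA_1	Eukaryotic-type carbonic anhydrase
ASP_PROTEASE	Retroviral aspartyl protease,Eukaryotic aspartyl protease
ATPASE_ALPHA_BETA	ATP synthase alpha/beta family
CARBOXYLESTERASE_B_1	Carboxylesterase family,Alpha/beta hydrolase fold
CYTOCHROME_P450	Cytochrome P450
EF_HAND	EF-hand,EF,Dockerin,Secreted
EGF_1	Laminin EGF-like,hEGF,EGF-like domain,Ca-binding EGF
IG_MHC	IG C1 Set,IG V Set
INSULIN	Insulin/IGF/Relaxin family,Nematode insulin-related peptide beta type
LACTALBUMIN_LYSOZYME	C-type lysozyme/alpha-lactalbumin family
LECTIN_LEGUME_BETA	Lectin_legB
PA2_HIS	Phospholip_A2_1,Phospholipase A2,PLA2G12
PROTEIN_KINASE_ST	Protein kinase domain,Protein tyrosine kinase
PROTEIN_KINASE_TYR	Protein tyrosine kinase,Protein kinase domain,RIO1 family,Lipopolysaccharide kinase (Kdo/WaaP) family
RNASE_PANCREATIC	Pancreatic ribonuclease
SOD_CU_ZN_1	Copper/zinc superoxide dismutase
TRYPSIN_HIS	TRYPSIN
TRYPSIN_SER	TRYPSIN,Immunoglobulin A1 Protease
ZINC_PROTEASE
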