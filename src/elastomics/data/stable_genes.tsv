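entrez_id	gene_id	association	gene_name
84935	MEDAG	Stiff	Mesenteric estrogen dependent Adipogenesis
1378	CR1	Stiff	Complement C3b/C4b receptor 1 (Knops blood group)
23213	SULF1	Stiff	Sulfatase 1
3875	KRT18	Stiff	Keratin 18
9332	CD163	Stiff	CD163 molecule
100628315	DNM3OS	Stiff	DNM3 opposite strand/antisense RNA
728264	CARMN	Stiff	Cardiac mesoderm enhancer-associated noncoding RNA
5325	PLAGL1	Stiff	PLAG1 like zinc finger 1
8829	NRP1	Stiff	Neuropilin 1
54885	TBC1D8B	Stiff	TBC1 domain family member 8B
7373	COL14A1	Stiff	Collagen type XIV alpha 1 chain
1282	COL4A1	Stiff	Collagen type IV alpha 1 chain
79839	CCDC102B	Stiff	Coiled-coil domain containing 102B
1601	DAB2	Stiff	DAB adaptor protein 2
3672	ITGA1	Stiff	Integrin subunit alpha 1
4121	MAN1A1	Stiff	Mannosidase alpha class 1A member 1
55075	UACA	Stiff	Uveal autoantigen with coiled-coil domains and ankyrin repeats
5205	ATP8B1	Stiff	ATPase phospholipid transporting 8B1
5139	PDE3A	Stiff	Phosphodiesterase 3A
22925	PLA2R1	Stiff	Phospholipase A2 receptor 1
5592	PRKG1	Stiff	Protein kinase cGMP-dependent 1
1909	EDNRA	Stiff	Endothelin receptor type A
1290	COL5A2	Stiff	Collagen type V alpha 2 chain
1368	CPM	Stiff	Carboxypeptidase M
9060	PAPSS2	Stiff	3'-phosphoadenosine 5'-phosphosulfate synthase 2
10351	ABCA8	Stiff	ATP binding cassette subfamily A member 8
8654	PDE5A	Stiff	Phosphodiesterase 5A
3759	KCNJ2	Stiff	Potassium inwardly rectifying channel subfamily J member 2
5175	PECAM1	Stiff	Platelet and endothelial cell adhesion molecule 1
2321	FLT1	Stiff	Fms related receptor tyrosine kinase 1
115548	FCHO2	Stiff	FCH and mu domain containing endocytic adaptor 2
84910	TMEM87B	Stiff	Transmembrane protein 87B
9169	SCAF11	Stiff	SR-related CTD associated factor 11
23216	TBC1D1	Stiff	TBC1 domain family member 1
2803	GOLGA4	Stiff	Golgin A4
875	CBS	Soft	Cystathionine beta-synthase
728875	LINC00623	Soft	Long intergenic non-protein coding RNA 623
93145	OLFM2	Soft	Olfactomedin 2
1600	DAB1	Soft	DAB adaptor protein 1
767	CA8	Soft	Carbonic anhydrase 8
441381	LRRC24	Soft	Leucine rich repeat containing 24
81551	STMN4	Soft	Stathmin 4
345630	FBLL1	Soft	Fibrillarin like 1
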