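accession	description	experiments_observed_NSC	sum_count_NSC
IPI00575509	CCT5 T-complex protein 1 subunit epsilon (TCP1)	3	14
IPI00589671	TTC38 Tetratricopeptide repeat protein 38	1	4
IPI00576535	ANXA6 Annexin A6	3	14
IPI00573783	PRKAR1A cAMP-dependent protein kinase type I-alpha regulatory subunit	1	4
IPI00591329	LOC429161 similar to otolin-1	3	12
IPI00579627	CRMP1 Collapsin response mediator protein-1A	1	4
IPI00811766	PPP2R1B Protein phosphatase 2, regulatory subunit A, beta	3	8
IPI00591218	MOSC2 similar to MOCO sulphurase C-terminal domain containing 2	1	4
IPI00600895	ALAD Delta-aminolevulinic acid dehydratase	3	5
IPI00589157	GNAI2 Guanine nucleotide-binding protein G(i) subunit alpha-2	1	4
IPI00591901	LOC395261 Filamin	2	21
IPI00585015	RCJMB04_1g23 Cytoplasmic dynein 1 light intermediate chain 2	1	4
IPI00602654	DDOST Dolichyl-diphosphooligosaccharide-protein glycosyltransferase	2	19
IPI00592494	RCJMB04_7k22 Septin9	1	4
IPI00584755	CKAP4 Cytoskeleton-associated protein 4	2	13
IPI00572509	NCSTN Nicastrin	1	3
IPI00601716	PSMD13 26S proteasome non-ATPase regulatory subunit 13	2	12
IPI00595745	PDHA1 Pyruvate dehydrogenase E1	1	3
IPI00595381	IMMT Mitochondrial inner membrane protein	2	7
IPI00651204	RCJMB04_1d17 Regulation of nuclear pre-mRNA domain-containing protein 1B	1	3
IPI00821733	ACAD9 Acyl-CoA dehydrogenase family member 9	2	6
IPI00589812	ANP32A Acidic leucine-rich nuclear phosphoprotein 32 family member A	1	3
IPI00682371	SDHA Succinate dehydrogenase	2	6
IPI00602199	ADD1 Alpha-adducin	1	3
IPI00593255	EIF3E Eukaryotic translation initiation factor 3 subunit E	2	6
IPI00572503	MAN2B2 similar to mannosidase, alpha, class 2B, member 2	1	3
IPI00575141	RCJMB04_9j22 RNA binding motif protein, X-linked	2	6
IPI00577333	GNA11 Guanine nucleotide-binding protein G11 alpha-subunit	1	3
IPI00601137	SMC1 Structural maintenance of chromosomes protein 1A	2	5
IPI00590033	EIF2S1 Eukaryotic translation initiation factor 2 subunit 1	1	3
IPI00579016	USP5 Ubiquitin carboxyl-terminal hydrolase 5	2	5
IPI00592268	POFUT1 GDP-fucose protein O-fucosyltransferase 1	1	3
IPI00588285	LRPAP1 Low density lipoprotein receptor-related protein associated protein 1	2	5
IPI00601449	UGP2 UTP—glucose-1-phosphate uridylyltransferase	1	3
IPI00818044	13 kDa protein Desru_0254	2	5
IPI00571138	EEA1 Early endosome antigen 1	1	3
IPI00584652	SEPT2 Septin-2	2	5
IPI00577749	BZW2 Basic leucine zipper and W2 domain-containing protein 2	1	3
IPI00590859	ATP2A2 Sarcoplasmic/endoplasmic reticulum calcium ATPase 2 (SERCA2)	2	4
IPI00580874	ATP1B3 Sodium/potassium-transporting ATPase subunit beta-3	1	3
IPI00588997	ARHGDIB similar to D4-GDP-dissociation inhibitor	2	4
IPI00599733	STAG2 similar to stromal antigen 2	1	3
IPI00573911	RRBP1 Ribosome-binding protein 1	2	4
IPI00602866	RCJMB04_12m17 Short/branched chain specific acyl-CoA dehydrogenase	1	3
IPI00582808	CSE1L similar to cellular apoptosis susceptibility protein	2	4
IPI00821206	PSMC1 26S protease regulatory subunit 4	1	3
IPI00679585	TMC6 Transmembrane channel-like protein 6	2	3
IPI00581857	PITPNB Phosphatidylinositol transfer protein, beta	1	3
IPI00600831	96 kDa protein Solute carrier family 12 member 2 (NKCC1)	2	3
IPI00599649	HHATL Hedgehog acyltransferase-like	1	3
IPI00592568	CKM Creatine kinase M-type	2	3
IPI00583448	RCJMB04_1m9 Thyroid hormone receptor associated protein 3	1	2
IPI00582661	AKT1 Serine/threonine protein kinase	2	3
IPI00593562	ATP13A3 similar to type V P-type ATPase	1	2
IPI00683271	TF Ovotransferrin	1	17
IPI00596507	COL18A1 collagen, type XVIII, alpha 1	1	2
IPI00682714	HADH similar to L-3-hydroxyacyl-Coenzyme A dehydrogenase	1	11
IPI00573599	PCYOX1 Prenylcysteine oxidase 1 precursor	1	2
IPI00601017	PSMD6 26S proteasome non-ATPase regulatory subunit 6	1	11
IPI00571239	TALDO1 Transaldolase	1	2
IPI00593882	LOC395260 Chicken gizzard actin-binding protein260	1	10
IPI00597630	PA2G4 similar to proliferation-associated protein 1, partial	1	2
IPI00585154	792 kDa protein Nesprin 2	1	9
IPI00584175	FDPS Farnesyl pyrophosphate synthase	1	2
IPI00584704	COL8A2 Collagen, type VIII, alpha 2	1	8
IPI00598610	PSMD11 26S proteasome subunit p44.5	1	2
IPI00599017	PRPS1 Ribose-phosphate pyrophosphokinase 1	1	8
IPI00574033	TXNDC10 Protein disulfide-isomerase TMX3	1	2
IPI00594100	SEC61A1 similar to sec61-like protein	1	7
IPI00574864	C14orf149 Proline racemase-like	1	2
IPI00573738	SERPINB14B Ovalbumin-related protein Y	1	7
IPI00575314	ERGIC1 Endoplasmic reticulum-golgi intermediate compartment (ERGIC) 1	1	2
IPI00587398	ACTR3 Actin-related protein 3	1	7
IPI00578250	COPS4 COP9 signalosome complex subunit 4	1	2
IPI00598417	P4HA1 similar to Prolyl 4-hydroxylase alpha-1 subunit	1	7
IPI00585168	SCLY Selenocysteine lyase	1	2
IPI00584282	CSNK2A1 Casein kinase II subunit alpha	1	7
IPI00587714	RPL27A Ribosomal protein L27a	1	2
IPI00589818	TACSTD1 Epithelial cell adhesion molecule	1	7
IPI00588179	C12orf10 Chromosome 12 open reading frame 10	1	2
IPI00582424	PSMD5 26S proteasome non-ATPase regulatory subunit 5	1	7
IPI00590550	NUMA1 Nuclear mitotic apparatus protein 1	1	2
IPI00573236	NANS Sialic acid synthase	1	6
IPI00591027	VAT1 similar to Vesicle amine transport protein 1 homolog	1	2
IPI00571322	DNAJB11 DnaJ (Hsp40) homolog, subfamily B	1	6
IPI00596498	CNOT1 similar to CCR4-NOT transcription complex, subunit 1	1	2
IPI00574127	PPP1R7 Protein phosphatase 1 regulatory subunit 7	1	5
IPI00596628	CARKD Carbohydrate kinase domain containing	1	2
IPI00587768	LOC429867 Plectin-1	1	5
IPI00596826	PAFAH1B1 Platelet-activating factor acetylhydrolase IB subunit alpha	1	2
IPI00584957	WDR61 WD repeat-containing protein 61	1	5
IPI00601344	SEC23B Protein transport protein Sec23A	1	2
IPI00585976	GNAI1 Guanine nucleotide-binding protein G(i) subunit alpha-1	1	5
IPI00575596	RPL4 Ribosomal protein L4	1	2
IPI00591767	LOC396473 Myristoylated alanine-rich C-kinase substrate	1	5
IPI00584214	FARSA Phenylalanyl-tRNA synthetase alpha chain	1	2
IPI00603208	GOLPH3 similar to trans-Golgi protein GMx33	1	5
IPI00812721	HDGF similar to hepatoma-derived growth factor	1	2
IPI00604247	RCJMB04_9n20 Isocitrate dehydrogenase [NAD] subunit beta	1	5
IPI00586160	CENPT Centromere protein T	1	2
IPI00592623	PSMD2 26S Proteasome non-ATPase regulatory subunit 2	1	4
IPI00575874	SPARC Osteonectin	1	2
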