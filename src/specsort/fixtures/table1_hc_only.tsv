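accession	description	experiments_observed_HC	sum_count_HC
IPI00576099	MYO7A similar to Myosin VIIA	3	21
IPI00575703	SNRPA1 U2 small nuclear ribonucleoprotein A	2	3
IPI00593631	GSTO1 similar to glutathione-S-transferase homolog isoform 2	3	15
IPI00590435	TOLLIP Toll-interacting protein	2	3
IPI00820937	PSMA1 Proteasome subunit alpha type-1	3	8
IPI00602158	LOC770724 NADH dehydrogenase [ubiquinone] 1 beta subcomplex subunit 6	2	3
IPI00590386	TLR3 Toll-like receptor 3	3	7
IPI00818913	HIP1 Huntingtin-interacting protein 1	1	5
IPI00571165	ACOT7 similar to acyl-CoA hydrolase	3	6
IPI00579531	SLC17A8 similar to vesicular glutamate transporter 3	1	4
IPI00579939	STARD10 StAR-related lipid transfer (START) domain	3	6
IPI00602683	20 kDa protein Mesencephalic astrocyte-derived neurotrophic factor precursor	1	4
IPI00589108	SCAMP1 similar to secretory carrier membrane protein 1	3	6
IPI00578232	ARL1 ADP-ribosylation factor-like 1	1	3
IPI00602403	CRABP1 Cellular retinoic acid-binding protein 1	2	13
IPI00597417	NDUFS4 similar to NADH dehydrogenase	1	3
IPI00594777	PGM2L1 Phosphoglucomutase 2-like 1	2	13
IPI00596633	TARDBP TAR DNA-binding protein 43	1	3
IPI00583929	PSMB1 Proteasome subunit beta type-1	2	11
IPI00578493	64 kDa protein Synapsin-3	1	3
IPI00601244	RAB7A similar to RAB7 protein	2	10
IPI00571302	TMEM35 Transmembrane protein 35	1	3
IPI00819526	RCJMB04_3m23 Vesicle-associated membrane protein-associated protein A	2	9
IPI00580720	APBA1 similar to adaptor protein X11alpha	1	3
IPI00582079	RAB2A Ras-related protein Rab-2A	2	7
IPI00584494	RCJMB04_1g4 Serine/arginine-rich splicing factor 10 isoform 2	1	3
IPI00582014	OSBPL1A similar to oxysterol-binding protein-like 1A isoform 2	2	7
IPI00590633	HSPH1 Heat shock protein 105 kDa	1	3
IPI00588689	PSMB2 Proteasome subunit beta type-2	2	7
IPI00580665	USP7 Ubiquitin specific peptidase 7	1	3
IPI00597497	RCJMB04_32c11 Elongation factor 1-beta	2	7
IPI00594943	ITPA Inosine triphosphate pyrophosphatase	1	2
IPI00599229	LOC776238 similar to rabconnectin	2	6
IPI00578052	MYL1 Myosin light chain 1, skeletal muscle isoform	1	2
IPI00577746	Eukaryotic translation initiation factor 5A-1	2	6
IPI00588407	KIF21A Kinesin family member 21A	1	2
IPI00571196	NDUFV2 similar to NADH dehydrogenase [ubiquinone] flavoprotein 2	2	6
IPI00576049	APOA1BP Apolipoprotein A-I binding protein	1	2
IPI00587613	LPGAT1 Lysophosphatidylglycerol acyltransferase 1	2	6
IPI00576667	ATP5I ATP synthase, H+ transporting	1	2
IPI00572839	NDUFS3 NADH dehydrogenase [ubiquinone] Fe-S protein 3 precursor	2	6
IPI00592914	RBBP4 Histone-binding protein RBBP4	1	2
IPI00603436	SNRPB Small nuclear ribonucleoprotein-associated protein B'	2	5
IPI00593252	ATP6V1H similar to 54 kDa vacuolar H(+)-ATPase subunit	1	2
IPI00579138	COX7A2L similar to cytochrome c oxidase polypeptide VIIa-heart	2	5
IPI00593747	ACSL4 similar to Acyl-CoA synthetase	1	2
IPI00594088	ATP5H ATP synthase subunit d	2	4
IPI00594946	BRWD2 Bromodomain and WD repeat-containing protein 2	1	2
IPI00576496	COX4I1 Cytochrome c oxidase subunit IV	2	4
IPI00597412	YKT6 Synaptobrevin homolog YKT6	1	2
IPI00812364	NDUFB4 NADH dehydrogenase [ubiquinone] 1 beta subcomplex subunit 4	2	4
IPI00601063	AIFM1 Apoptosis-inducing factor 1, mitochondrial	1	2
IPI00594618	SLC1A6 similar to neuronal glutamate transporter EAAT4	2	4
IPI00601775	RPL9 60S ribosomal protein L9	1	2
IPI00581287	LRP8 Low-density lipoprotein receptor-related protein 8	2	4
IPI00812461	STARD8 StAR-related lipid transfer (START) domain containing 8	1	2
IPI00602566	ABHD10 Abhydrolase domain containing 10	2	4
IPI00578195	ACP1 Low molecular weight phosphotyrosine protein phosphatase	1	2
IPI00586190	RPL24 similar to Ribosomal protein L24	2	3
IPI00578084	USO1 General vesicular transport factor p115	1	2
IPI00579860	ATP1B1 Sodium/potassium-transporting ATPase subunit beta-1	2	3
IPI00577046	INPP5F Phosphatidylinositide phosphatase SAC2	1	
IPI00596390	EFCAB6 EF-hand calcium binding domain 6	2	3
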