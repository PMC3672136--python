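accession	description	experiments_observed_total	sum_count_HC	sum_count_NSC	p_value
IPI00580273	SCCPDH Saccharopine dehydrogenase (putative)	4	1	34	8.9E-09
IPI00579247	RCJMB04_2a4 ATP-dependent RNA helicase DDX3X	4	1	14	0.0011
IPI00586709	TLN1 Talin-1	5	3	39	0.000000029
IPI00571140	SEC31A Protein transport protein Sec31A	2	1	12	0.0035
IPI00598955	SMC3 Structural maintenance of chromosomes protein 3	3	1	12	0.0035
IPI00679931	TXNDC4 similar to Thioredoxin domain containing 4	2	1	11	0.0061
IPI00588387	PARP1 Poly (ADP-ribose) polymerase 1	3	1	11	0.0061
IPI00601719	COL14A1 Collagen alpha-1(XIV) chain	2	1	10	0.011
IPI00572003	SERPINB6 Serpin B6	4	1	10	0.011
IPI00583720	DCPS Decapping enzyme, scavenger	2	1	10	0.011
IPI00591510	AKR1B10 Aldo-keto reductase family 1 member B10	3	2	19	0.00034
IPI00820020	AKR1A1 Alcohol dehydrogenase [NADP+]	3	1	9	0.018
IPI00585509	ACTR2 Actin-related protein 2	3	1	9	0.018
IPI00820163	HDLBP Vigilin	2	3	26	0.000034
IPI00573263	DST Dystonin	5	2	16	0.0016
IPI00582056	GSN Gelsolin	4	2	16	0.0016
IPI00735086	PGM1 Phosphoglucomutase 1	3	1	8	0.031
IPI00600960	AHCY similar to S-adenosylhomocysteine hydrolase	4	1	8	0.031
IPI00590654	PRPSAP2 Phosphoribosyl pyrophosphate synthase-associated protein 2	3	1	8	0.031
IPI00603965	KPNB1 Importin subunit beta-1	4	1	8	0.031
IPI00577774	RCJMB04_7e11 Isocitrate dehydrogenase 2	5	4	29	0.000028
IPI00572165	MYH9 Myosin-9	6	9	65	2.4E-10
IPI00589062	VCL Vinculin	5	8	56	6.1E-09
IPI00572461	ACTN4 Alpha-actinin-4	6	4	25	0.0002
IPI00570964	PGD 6-phosphogluconate dehydrogenase, decarboxylating	3	2	11	0.02
IPI00601873	PDHB similar to Pyruvate dehydrogenase (lipoamide) beta	3	2	11	0.02
IPI00598809	IDH1 similar to cytosolic NADP-dependent isocitrate dehydrogenase	5	9	49	0.00000059
IPI00591295	AKR1B1 Aldose reductase	3	4	19	0.0035
IPI00680028	NCL Nucleolin	5	3	14	0.013
IPI00576653	SEPHS1 Selenophosphate synthetase 1	2	3	14	0.013
IPI00577421	HSPD1 HSP60	5	9	40	0.000035
IPI00820593	HSP90AB1 Heat shock protein HSP 90-beta	4	11	47	0.037
IPI00600018	SERPINH1 Serpin H1	4	13	53	0.0000047
IPI00585747	EEF2 Elongation factor 2	6	17	69	0.00000019
IPI00585409	ANXA8L1 Annexin VIII	4	4	16	0.013
IPI00590350	HBG1;HBG2 Hemoglobin subunit beta	4	3	11	0.05
IPI00603318	CANX Calnexin	5	3	11	0.05
IPI00571411	Histone H1.03	5	6	21	0.008
IPI00600729	CTNNA1 Catenin alpha-1	5	4	14	0.03
IPI00571767	IQGAP1 RasGAP-like with IQ motif	4	8	26	0.0048
IPI00586516	PDIA6 Protein disulfide-isomerase A6 precursor	5	10	31	0.0029
IPI00684362	ALDH1A3 Retinaldehyde dehydrogenase 3	5	6	18	0.025
IPI00596315	GNB2L1 Guanine nucleotide-binding protein subunit beta-2-like 1	5	5	15	0.041
IPI00588683	ATP1A1 ATPase, Na+/K+ transporting, alpha 1 polypeptide	5	26	71	0.000048
IPI00592470	ANXA5 Annexin A5	6	42	114	0.00000033
IPI00589564	GOT1 Aspartate aminotransferase, cytoplasmic	4	7	19	0.033
IPI00588868	EIF4A2 Eukaryotic initiation factor 4A-II	6	18	47	0.0014
IPI00589958	PDIA4 Protein disulfide-isomerase A4 precursor	4	17	44	0.0021
IPI00570770	HSP90B1 Endoplasmin	6	49	126	0.00000032
IPI00584300	TCP1 T-complex protein 1 subunit alpha	4	7	18	0.046
IPI00579109	ACAT1 Acetyl-CoA acetyltransferase 1	5	9	23	0.026
IPI00596673	P4HB Protein disulfide-isomerase	5	19	48	0.0017
IPI00572635	IPO5 similar to Ran_GTP binding protein 5	3	8	20	0.04
IPI00577325	COPA Coatomer subunit alpha	5	12	29	0.018
IPI00576187	ACO2 Aconitase 2	5	15	33	0.022
IPI00578831	FLNB Filamin B	5	78	170	0.00000073
IPI00576130	MYH10 Nonmuscle myosin 10	5	41	79	0.0037
IPI00576318	FLNB Filamin	3	66	127	0.00027
IPI00590375	HSPA5 78 kDa glucose-regulated protein precursor	6	76	140	0.00041
IPI00572919	H4-VII Histone H4	5	33	58	0.029
IPI00577857	MDH2 similar to Malate dehydrogenase 2, NAD	6	39	68	0.021
IPI00820086	TPRXL Putative protein TPRXL	4	87	147	0.0021
IPI00589985	EEF1A1 Elongation factor 1-alpha 1	6	67	108	0.016
IPI00818934	VYGIII Vitellognin 3	5	84	132	0.013
IPI00583974	SERPINB14 Ovalbumin	4	148	230	0.0019
IPI00594653	GAPDH Glyceraldehyde-3-phosphate dehydrogenase	6	123	188	0.0068
IPI00572084	RCJMB04_1h13 Actin, cytoplasmic type 5	6	225	309	0.02
IPI00580626	TUBB2C Tubulin beta-3 chain	5	155	167	0.00054
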