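accession	description	experiments_observed_total	sum_count_HC	sum_count_NSC	p_value
IPI00599487	OTOF similar to brain otoferlin	5	321	17	0
IPI00571711	AK1 Adenylate kinase isoenzyme 1	4	17	1	0.000023
IPI00584789	ATP6V1B2 V-type proton ATPase subunit B, brain isoform	3	14	1	0.00019
IPI00576073	THOC4 THO complex 4	4	13	1	0.00039
IPI00596886	RPL10A 60S ribosomal protein L10a	3	12	1	0.00078
IPI00598353	CALB2 Calretinin	5	107	9	7.9E-26
IPI00584482	RPS10 Ribosomal protein S10	3	11	1	0.0016
IPI00602026	OCM2 Parvalbumin	5	30	3	0.0000001
IPI00583177	ATP6V1E1 ATPase, H+ transporting, lysosomal 31kDa, V1 subunit E1	4	10	1	0.0031
IPI00588963	FKBP3 FK506 binding protein 3	4	10	1	0.0031
IPI00582881	RAB14 Ras-related protein Rab-14	3	9	1	0.006
IPI00597483	ARL6IP5 ADP-ribosylation-like factor 6 interacting protein 5	3	9	1	0.006
IPI00603045	PEBP1 similar to Phosphatidylethanolamine-binding protein 1	4	16	2	0.00024
IPI00595127	SNAP91 Clathrin coat assembly protein AP180	3	8	1	0.012
IPI00598537	HSD17B10 Hydroxysteroid (17-beta) dehydrogenase 10	4	8	1	0.012
IPI00570686	ATP5F1 ATP synthase B chain	4	22	3	0.00002
IPI00595105	UCHL1 Ubiquitin carboxyl-terminal hydrolase isozyme L1	3	7	1	0.023
IPI00591896	DCI similar to Dodecenoyl-Coenzyme A delta isomerase	4	7	1	0.023
IPI00572880	MYO6 Isoform 1 of Myosin-VI	5	150	22	4.9E-29
IPI00591852	YWHAB 14-3-3 protein beta/alpha	4	33	5	0.00000028
IPI00580943	317 kDa protein Lipopolysaccharide-responsive and beige-like anchor protein isoform 2	4	19	3	0.00013
IPI00818110	ATP6V0A1 V-type proton ATPase	4	6	1	0.043
IPI00589575	ALDH2 Aldehyde dehydrogenase 2 family (mitochondrial)	4	28	5	0.0000062
IPI00583615	RCJMB04_15c3 Vesicle-trafficking protein SEC22b	4	11	2	0.0058
IPI00823023	MAP1B Microtubule-associated protein 1B	4	41	8	0.000000089
IPI00813389	ATP5O ATP synthase	3	9	2	0.019
IPI00577117	ME1 Malic enzyme	3	9	2	0.019
IPI00573597	HSPA4L Heat shock 70kDa protein 4-like	3	9	2	0.019
IPI00573563	RAB11B	3	9	2	0.019
IPI00601849	INPP5K Inositol polyphosphate 5-phosphatase K	3	9	2	0.019
IPI00684373	RAB1A	5	26	6	0.000062
IPI00577014	CBR1 20-hydroxysteroid dehydrogenase	4	8	2	0.035
IPI00598533	SOD1 Superoxide dismutase [Cu-Zn]	3	8	2	0.035
IPI00597655	RCJMB04_24f23 Endoplasmic reticulum resident protein 29	5	11	3	0.016
IPI00579550	ATP6V1A ATPase, H+ transporting, lysosomal 70kDa, V1 subunit A	4	10	3	0.027
IPI00822785	ARF1 ADP-ribosylation factor 1	4	56	18	0.00000033
IPI00585707	RCJMB04_1d23 Rho GDP dissociation inhibitor (GDI) alpha	5	18	6	0.0045
IPI00683666	CLTCL1 similar to Clathrin, heavy polypeptide	4	112	41	9.3E-10
IPI00573447	SLC25A3 Solute carrier family 25 member 3	5	12	5	0.041
IPI00829409	CLTC clathrin heavy chain 1	6	295	124	2.6E-23
IPI00574627	PHB Prohibitin	4	20	9	0.013
IPI00575808	ACLY ATP citrate lyase	4	33	15	0.0016
IPI00600989	SLC25A6 ADP/ATP translocase 3	6	33	18	0.007
IPI00604016	CKB Isoform Bb-CK-2 of Creatine kinase B-type	6	236	131	5E-12
IPI00578632	RCJMB04_11l21 14-3-3 protein zeta	6	45	27	0.0048
IPI00596765	GSTA3 Glutathione S-transferase	5	25	15	0.032
IPI00582452	TPI1 Triosephosphate isomerase	6	41	26	0.012
IPI00600992	LOC429558 similar to histone H2B	6	51	34	0.009
IPI00953851	PPIA Peptidyl-prolyl cis-trans isomerase	6	37	26	0.036
IPI00577739	YWHAQ 14-3-3 protein theta	6	34	24	0.044
IPI00603718	TUBB3 Tubulin beta-4 chain	4	120	93	0.00058
IPI00575860	DYNC1H1 similar to dynein, cytoplasmic, heavy polypeptide 1	5	153	127	0.0041
IPI00575989	TUBA1C Tubulin alpha-1 chain (Fragment)	6	167	152	0.022
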