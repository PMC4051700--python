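species_label	bin_id	specimen_count	label_rank	suspect_misid	is_reference_bin	table_category	reference_country	detected_in	occupancy_notes
C. argus	ABW0047	35	species	0	1	MATCH	China	USA
C. asiatica	AAW6834	1	species	0	1	SPLIT	Unknown
C. asiatica	ACH5880	1	species	0	1	SPLIT	China
C. asiatica	ACH5881	3	species	0	1	SPLIT	China
C. aurantimaculata	AAF3792	8	species	0	1	MATCH	India	USA
C. bankanensis	AAI7246	2	species	0	1	MATCH	Unknown
C. barca	ACB7513	5	species	0	1	MATCH	India
C. bleheri	AAE1408	7	species	0	1	MATCH	India
C. burmanica	ACG5458	1	species	0	1	MATCH	Myanmar
C. diplogramma	AAD7592	10	species	0	1	MATCH	India
C. gachua	ABV9993	1	species	0	1	SPLIT	Thailand
C. gachua	ABV9969	1	species	0	1	SPLIT	Thailand
C. gachua	ABV9996	1	species	0	1	SPLIT	Thailand
C. gachua	AAC3926	1	species	0	1	SPLIT	Myanmar
C. gachua	ABV9994	1	species	0	1	SPLIT	Thailand
C. gachua	AAC3925	7	species	0	1	SPLIT	Myanmar & Thailand
C. gachua	AAC3927	5	species	0	1	SPLIT	Thailand
C. gachua	AAC3928	2	species	0	1	SPLIT	India
C. gachua	ACB7510	2	species	0	1	SPLIT	Indonesia
C. gachua	ACB8348	5	species	0	1	SPLIT	India
C. species	ABW0050	1	genus_only	0	1	MATCH	Indonesia		single specimen named only to genus; not counted among the 25 species
C. lucius	AAW6833	1	species	0	1	SPLIT	Malaysia
C. lucius	ABW0051	5	species	0	1	SPLIT	Malaysia & Thailand
C. maculata	ABW0048	1	species	0	1	MIXTURE	Vietnam, China	Canada & USA	heterogeneous cluster of 17: 9 C. sp., 1 C. maculata, 6 GenBank C. argus, 1 hybrid
C. sp.	ABW0048	9	genus_only	0	1			Canada	market/wild British Columbia specimens named only to genus
C. argus	ABW0048	6	species	1	1			China	GenBank C. argus presumed misidentified C. maculata or hybrid-derived
C. argus (male) x C. maculata (female)	ABW0048	1	hybrid	0	1			China	aquaculture hybrid; maternal C. maculata lineage
C. marulius	ABW0012	7	species	0	0	SPLIT	N/A	Canada & USA	non-native Florida/pet-trade cluster with no reference specimens
C. marulius	AAI7187	10	species	0	1	SPLIT	India
C. cf. marulius	AAC6049	1	provisional	0	1		Unknown		provisional label; separate row, excluded from the 25-species tally
C. melasoma	ABW1864	1	species	0	1	MATCH	Singapore
C. micropeltes	AAD2426	12	species	0	1	MATCH	Thailand	Canada & USA
C. orientalis	ABV9995	1	species	0	1	SPLIT	India
C. orientalis	AAC6050	6	species	0	1	SPLIT	India & Myanmar
C. orientalis	ACA9095	5	species	0	1	SPLIT	India
C. orientalis	ABA8489	1	species	0	1	SPLIT	India
C. ornatipinnis	AAW6831	1	species	0	1	MATCH	Unknown
C. panaw	ABW1866	1	species	0	0	MATCH	N/A	Denmark	introduced specimen; no reference barcode available
C. pleurophthalmus	AAI7162	2	species	0	1	MATCH	Unknown
C. pulchra	AAF3770	3	species	0	1	MATCH	Unknown
C. punctata	AAE8814	16	species	0	1	SPLIT	India, Myanmar
C. punctata	ACG5323	1	species	0	1	SPLIT	Myanmar
C. stewartii	AAF3764	8	species	0	1	SPLIT	India
C. stewartii	AAF3772	3	species	0	1	SPLIT	India & Thailand
C. cf. stewartii	AAC6053	1	provisional	0	1		Unknown		provisional label; separate row, excluded from the 25-species tally
C. striata	AAB2497	23	species	0	1	SPLIT	Indonesia, Thailand	Philippines & USA
C. striata	ACB7973	6	species	0	1	SPLIT	India (Assam)
C. striata	AAB2498	2	species	0	1	SPLIT	India (Tamil Nadu)
P. africana	AAF7843	3	species	0	1	MIXTURE	Democratic Republic of the Congo		cluster of 4: three P. africana plus one P. obscura occupant
P. obscura	AAF7843	1	species	1	1				P. obscura occupant of the P. africana cluster; flagged suspect so P. obscura itself stays a single pure cluster
P. insignis	ABW0157	4	species	0	1	SPLIT	Democratic Republic of the Congo, Republic of the Congo
P. insignis	ACE8403	1	species	0	1	SPLIT
P. obscura	AAF7842	7	species	0	1	MATCH	Nigeria, Senegal
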