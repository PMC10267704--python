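# Replication-cohort genotype tallies (long form) for the 61-variant
# validation panel rows whose per-group carrier counts were published.
# Carrier counts from "X + Y vs Z" collapsed rows are encoded as het; the
# dominant-model collapse is invariant to the het/hom_alt split.
# The PCNXL2 row is monomorphic in both groups; its per-group totals were
# not published, so the 381/381 totals here are synthetic placeholders that
# only exercise the single-genotype-class (not_available) path.
variant	gene	rs_id	group	genotype	count
chr1:233386580T>C	PCNXL2	rs759917992	case	hom_ref	381
chr1:233386580T>C	PCNXL2	rs759917992	control	hom_ref	381
chr1:3638706C>T	TP73	rs1641123267	case	het	1
chr1:3638706C>T	TP73	rs1641123267	case	hom_ref	378
chr1:3638706C>T	TP73	rs1641123267	control	het	0
chr1:3638706C>T	TP73	rs1641123267	control	hom_ref	365
chr11:6231170C>T	C11orf42	rs751350529	case	het	0
chr11:6231170C>T	C11orf42	rs751350529	case	hom_ref	379
chr11:6231170C>T	C11orf42	rs751350529	control	het	2
chr11:6231170C>T	C11orf42	rs751350529	control	hom_ref	378
chr11:6231682G>A	C11orf42	rs749213397	case	het	0
chr11:6231682G>A	C11orf42	rs749213397	case	hom_ref	380
chr11:6231682G>A	C11orf42	rs749213397	control	het	3
chr11:6231682G>A	C11orf42	rs749213397	control	hom_ref	371
chr12:113385843GC>G	OAS3	rs771052891	case	het	6
chr12:113385843GC>G	OAS3	rs771052891	case	hom_ref	374
chr12:113385843GC>G	OAS3	rs771052891	control	het	2
chr12:113385843GC>G	OAS3	rs771052891	control	hom_ref	368
chr12:40834995T>A	MUC19	rs1411441474	case	het	2
chr12:40834995T>A	MUC19	rs1411441474	case	hom_ref	378
chr12:40834995T>A	MUC19	rs1411441474	control	het	6
chr12:40834995T>A	MUC19	rs1411441474	control	hom_ref	366
chr12:8998099G>A	A2ML1	rs766100204	case	het	2
chr12:8998099G>A	A2ML1	rs766100204	case	hom_ref	372
chr12:8998099G>A	A2ML1	rs766100204	control	het	1
chr12:8998099G>A	A2ML1	rs766100204	control	hom_ref	362
chr14:59782026G>T	DAAM1	.	case	het	1
chr14:59782026G>T	DAAM1	.	case	hom_ref	377
chr14:59782026G>T	DAAM1	.	control	het	0
chr14:59782026G>T	DAAM1	.	control	hom_ref	364
chr14:64519635A>T	SYNE2	rs777169796	case	het	1
chr14:64519635A>T	SYNE2	rs777169796	case	hom_ref	377
chr14:64519635A>T	SYNE2	rs777169796	control	het	0
chr14:64519635A>T	SYNE2	rs777169796	control	hom_ref	354
chr17:48185985C>T	PDK2	rs748085033	case	het	1
chr17:48185985C>T	PDK2	rs748085033	case	hom_ref	379
chr17:48185985C>T	PDK2	rs748085033	control	het	1
chr17:48185985C>T	PDK2	rs748085033	control	hom_ref	381
chr17:56281773C>T	EPX	rs757233476	case	het	1
chr17:56281773C>T	EPX	rs757233476	case	hom_ref	378
chr17:56281773C>T	EPX	rs757233476	control	het	0
chr17:56281773C>T	EPX	rs757233476	control	hom_ref	381
chr19:10079057TCACAGGGTCTCC>T	COL5A3	.	case	het	1
chr19:10079057TCACAGGGTCTCC>T	COL5A3	.	case	hom_ref	378
chr19:10079057TCACAGGGTCTCC>T	COL5A3	.	control	het	0
chr19:10079057TCACAGGGTCTCC>T	COL5A3	.	control	hom_ref	381
chr19:10479075GAAGC>G	TYK2	.	case	het	1
chr19:10479075GAAGC>G	TYK2	.	case	hom_ref	379
chr19:10479075GAAGC>G	TYK2	.	control	het	10
chr19:10479075GAAGC>G	TYK2	.	control	hom_ref	365
chr19:18981025ACGGGGGCG>A	GDF1	rs1568291627	case	het	1
chr19:18981025ACGGGGGCG>A	GDF1	rs1568291627	case	hom_ref	380
chr19:18981025ACGGGGGCG>A	GDF1	rs1568291627	control	het	1
chr19:18981025ACGGGGGCG>A	GDF1	rs1568291627	control	hom_ref	363
chr19:33464372C>CTT	C19orf40	rs760353712	case	het	1
chr19:33464372C>CTT	C19orf40	rs760353712	case	hom_ref	376
chr19:33464372C>CTT	C19orf40	rs760353712	control	het	0
chr19:33464372C>CTT	C19orf40	rs760353712	control	hom_ref	378
chr19:50528523C>G	VRK3	rs1048569809	case	het	4
chr19:50528523C>G	VRK3	rs1048569809	case	hom_ref	376
chr19:50528523C>G	VRK3	rs1048569809	control	het	1
chr19:50528523C>G	VRK3	rs1048569809	control	hom_ref	379
chr2:179320735A>G	DFNB59	rs1437628682	case	het	1
chr2:179320735A>G	DFNB59	rs1437628682	case	hom_ref	66
chr2:179320735A>G	DFNB59	rs1437628682	control	het	0
chr2:179320735A>G	DFNB59	rs1437628682	control	hom_ref	103
chr2:63486522T>TC	WDPCP	.	case	het	1
chr2:63486522T>TC	WDPCP	.	case	hom_ref	379
chr2:63486522T>TC	WDPCP	.	control	het	0
chr2:63486522T>TC	WDPCP	.	control	hom_ref	345
chr20:1546854GC>GCC	SIRPB1	rs1275744950	case	het	9
chr20:1546854GC>GCC	SIRPB1	rs1275744950	case	hom_ref	372
chr20:1546854GC>GCC	SIRPB1	rs1275744950	control	het	2
chr20:1546854GC>GCC	SIRPB1	rs1275744950	control	hom_ref	379
chr20:34214629C>CT	CPNE1	.	case	het	1
chr20:34214629C>CT	CPNE1	.	case	hom_ref	379
chr20:34214629C>CT	CPNE1	.	control	het	0
chr20:34214629C>CT	CPNE1	.	control	hom_ref	380
chr3:121341344CT>C	FBXO40	.	case	het	1
chr3:121341344CT>C	FBXO40	.	case	hom_ref	378
chr3:121341344CT>C	FBXO40	.	control	het	0
chr3:121341344CT>C	FBXO40	.	control	hom_ref	379
chr4:146572222C>T	MMAA	rs757548934	case	het	1
chr4:146572222C>T	MMAA	rs757548934	case	hom_ref	379
chr4:146572222C>T	MMAA	rs757548934	control	het	0
chr4:146572222C>T	MMAA	rs757548934	control	hom_ref	339
chr4:9922067C>T	SLC2A9	.	case	het	0
chr4:9922067C>T	SLC2A9	.	case	hom_ref	380
chr4:9922067C>T	SLC2A9	.	control	het	1
chr4:9922067C>T	SLC2A9	.	control	hom_ref	381
chr5:135273232C>A	FBXL21P	rs201662172	case	het	1
chr5:135273232C>A	FBXL21P	rs201662172	case	hom_ref	378
chr5:135273232C>A	FBXL21P	rs201662172	control	het	0
chr5:135273232C>A	FBXL21P	rs201662172	control	hom_ref	379
chr5:141336148C>T	PCDH12	.	case	het	1
chr5:141336148C>T	PCDH12	.	case	hom_ref	379
chr5:141336148C>T	PCDH12	.	control	het	10
chr5:141336148C>T	PCDH12	.	control	hom_ref	370
chr6:7329418G>A	CAGE1	rs1414911763	case	het	0
chr6:7329418G>A	CAGE1	rs1414911763	case	hom_ref	174
chr6:7329418G>A	CAGE1	rs1414911763	control	het	23
chr6:7329418G>A	CAGE1	rs1414911763	control	hom_ref	209
chr7:7758145C>G	RPA3	rs529874466	case	het	1
chr7:7758145C>G	RPA3	rs529874466	case	hom_ref	372
chr7:7758145C>G	RPA3	rs529874466	control	het	1
chr7:7758145C>G	RPA3	rs529874466	control	hom_ref	314
chr9:117568285T>C	TNFSF15	.	case	het	2
chr9:117568285T>C	TNFSF15	.	case	hom_ref	379
chr9:117568285T>C	TNFSF15	.	control	het	0
chr9:117568285T>C	TNFSF15	.	control	hom_ref	381
chr9:130265135G>A	LRSAM1	rs770106776	case	het	1
chr9:130265135G>A	LRSAM1	rs770106776	case	hom_ref	378
chr9:130265135G>A	LRSAM1	rs770106776	control	het	2
chr9:130265135G>A	LRSAM1	rs770106776	control	hom_ref	371
chr9:133245203G>A	HMCN2	rs1445146226	case	het	1
chr9:133245203G>A	HMCN2	rs1445146226	case	hom_ref	378
chr9:133245203G>A	HMCN2	rs1445146226	control	het	0
chr9:133245203G>A	HMCN2	rs1445146226	control	hom_ref	381
chr9:139301649C>G	SDCCAG3	rs375609278	case	het	0
chr9:139301649C>G	SDCCAG3	rs375609278	case	hom_ref	380
chr9:139301649C>G	SDCCAG3	rs375609278	control	het	1
chr9:139301649C>G	SDCCAG3	rs375609278	control	hom_ref	364
chr9:78973443C>T	PCSK5	rs769457551	case	het	1
chr9:78973443C>T	PCSK5	rs769457551	case	hom_ref	379
chr9:78973443C>T	PCSK5	rs769457551	control	het	1
chr9:78973443C>T	PCSK5	rs769457551	control	hom_ref	379
chr12:40882387TA>T	MUC19	rs112524759	case	het	97
chr12:40882387TA>T	MUC19	rs112524759	case	hom_ref	282
chr12:40882387TA>T	MUC19	rs112524759	control	het	94
chr12:40882387TA>T	MUC19	rs112524759	control	hom_ref	276
chr16:14041622C>A	ERCC4	rs2020959	case	het	1
chr16:14041622C>A	ERCC4	rs2020959	case	hom_ref	376
chr16:14041622C>A	ERCC4	rs2020959	control	het	0
chr16:14041622C>A	ERCC4	rs2020959	control	hom_ref	363
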