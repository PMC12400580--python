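compound_id	name	chemical_class	herb_ids	quality_control_marker
CB001	Quercetin	flavonoid	BHSSC,GQZ,TSZ,HZ,DS	false
CB002	Kaempferol	flavonoid	BHSSC	false
CB003	Kaempferol-3-glucorhamnoside	flavonoid	BHSSC	true
CB004	Rutin	flavonoid	BHSSC,HZ	false
CB005	Luteolin	flavonoid	DS	false
CB006	Apigenin	flavonoid	DS	false
CB007	Isoquercitrin	flavonoid	GQZ	false
CB008	Hyperoside	flavonoid	TSZ	false
CB009	Astragalin	flavonoid	TSZ	false
CB010	Naringenin	flavonoid	BHSSC	false
CB011	Chrysin	flavonoid	HZ	false
CB012	Baicalein	flavonoid	HZ	false
CB013	Genistein	flavonoid	TSZ	false
CB014	Daidzein	flavonoid	TSZ	false
CB015	Syringin	terpenoid	CWJ	true
CB016	Atractylenolide I	terpenoid	BZ	false
CB017	Atractylenolide II	terpenoid	BZ	false
CB018	Atractylenolide III	terpenoid	BZ	false
CB019	Pachymic acid	terpenoid	FL	false
CB020	Dehydrotumulosic acid	terpenoid	FL	false
CB021	Oleanolic acid	terpenoid	NZZ,GQZ	false
CB022	Ursolic acid	terpenoid	NZZ	false
CB023	Betulinic acid	terpenoid	HZ	false
CB024	Schisandrin	lignan	WWZ	true
CB025	Schisandrol A	lignan	WWZ	false
CB026	Schisandrin B	lignan	WWZ	false
CB027	Schisandrin C	lignan	WWZ	false
CB028	Schisantherin A	lignan	WWZ	false
CB029	Gomisin A	lignan	WWZ	false
CB030	Gomisin J	lignan	WWZ	false
CB031	Pregomisin	lignan	WWZ	false
CB032	Isofraxidin	coumarin	CWJ	false
CB033	Eleutheroside B1	coumarin	CWJ	false
CB034	Scopoletin	coumarin	GQZ,TSZ	false
CB035	Umbelliferone	coumarin	HZ	false
CB036	Esculetin	coumarin	HZ	false
CB037	Salidroside	phenylethanoid glycoside	NZZ	true
CB038	3-Hydroxytyrosol 3-O-glucoside	phenylethanoid glycoside	NZZ	true
CB039	Cimidahurinine	phenylethanoid glycoside	BZ	false
CB040	Acteoside	phenylethanoid glycoside	NZZ	false
CB041	Chlorogenic acid	phenolic acid	TSZ,GQZ	false
CB042	Caffeic acid	phenolic acid	DS,HZ	false
CB043	Protocatechuic acid	phenolic acid	BHSSC	false
CB044	Atractylone	volatile oil	BZ	false
CB045	beta-Eudesmol	volatile oil	BZ	false
CB046	alpha-Pinene	volatile oil	CWJ	false
CB047	Lobetyolin	polyacetylene	DS	false
CB048	Atractylodin	polyacetylene	BZ	false
CB049	Betaine	amino acid	GQZ	false
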