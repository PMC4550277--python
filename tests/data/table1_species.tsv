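species	common_name	eggs	collections
Citharichthys stigmaeus	Speckled Sanddab	4317	228
Oxyjulis californica	Senorita	4075	134
Sardinops sagax	Pacific Sardine	1249	31
Engraulis mordax	Northern Anchovy	639	40
Xenistius californiensis	Californian Salema	541	40
Menticirrhus undulatus	California Corbina	394	52
Citharichthys sordidus	Pacific Sanddab	393	106
Roncador stearnsii	Spotfin Croaker	258	43
Paralichthys californicus	California Halibut	234	89
Halichoeres semicinctus	Rock Wrasse	230	64
Seriphus politus	Queenfish	210	32
Trachurus symmetricus	Pacific Jack Mackerel	112	20
Hypsopsetta guttulata	Diamond Turbot	85	54
Paralabrax clathratus	Kelp Bass	82	36
Semicossyphus pulcher	Sheephead	80	39
Citharichthys xanthostigma	Longfin Sanddab	57	32
Cheilotrema saturnum	Black Croaker	40	22
Scomber japonicus	Chub Mackerel	38	13
Genyonemus lineatus	White Croaker	33	12
Anisotremus davidsonii	Xantic Sargo	25	9
Peprilus simillimus	Pacific Pompano	24	16
Cynoscion parvipinnis	Shortfin Corvina	23	12
Chilara taylori	Spotted Cusk-eel	17	14
Atractoscion nobilis	White Seabass	16	7
Symphurus atricaudus	California Tonguefish	15	10
Paralabrax nebulifer	Barred Sand Bass	12	10
Xystreurys liolepis	Fantail Sole	11	3
Umbrina roncador	Yellowfin Croaker	10	5
Pleuronichthys verticalis	Hornyhead Turbot	6	4
Pleuronichthys coenosus	C-O Sole	5	5
Caulolatilus princeps	Ocean Whitefish	5	4
Girella nigricans	Opaleye	4	3
Sphyraena argentea	Pacific Barracuda	4	2
Synodus lucioceps	California Lizardfish	2	1
Hypsoblennius jenkinsi	Mussel Blenny	2	2
Paralabrax maculatofasciatus	Spotted Sand Bass	2	2
Stereolepis gigas	Giant Sea Bass	1	1
Citharichthys fragilis	Gulf Sanddab	1	1
Hermosilla azurea	Zebra-perch Sea Chub	1	1
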