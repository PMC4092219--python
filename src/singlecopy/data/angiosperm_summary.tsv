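genome	total_genes	n_single_copy	n_singletons	n_blocks
Aquilegia_coerulea	24823	4962	1886	65
Arabidopsis_lyrata	32670	4863	1710	89
Arabidopsis_thaliana	27382	4285	919	211
Brachypodium_distachyon	26552	3987	733	151
Brassica_rapa	41019	3098	1366	745
Capsella_rubella	26521	3613	393	179
Carica_papaya	27584	8292	3377	60
Citrus_clementina	24533	4550	876	131
Citrus_sinensis	25379	4883	946	111
Cucumis_sativus	21458	4778	1309	149
Eucalyptus_grandis	36376	6897	3930	316
Fragaria_vesca	32831	6132	3547	122
Glycine_max	45272	3687	2348	777
Gossypium_raimondii	37505	3823	1456	801
Manihot_esculenta	30666	3788	672	476
Mimulus_guttatus	26718	4081	724	266
Oryza_sativa	55565	9995	6829	160
Phaseolus_vulgaris	27197	3760	554	342
Populus_trichocarpa	40668	4435	2502	544
Prunus_persica	27864	3922	689	122
Ricinus_communis	31221	11095	7206	115
Setaria_italica	35471	7608	4130	154
Solanum_lycopersicum	34727	6274	2687	317
Solanum_tuberosum	35119	5665	2388	238
Sorghum_bicolor	33032	6761	3399	152
Thellungiella_halophila	26351	3676	511	177
Theobroma_cacao	29408	7226	3434	139
Vitis_vinifera	26346	5684	2501	143
Zea_mays	39656	6184	3307	383
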