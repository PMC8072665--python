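ID	Name	OB	DL	Medical plants
MOL000359	Sitosterol	36.91	0.75	RRP, RD, FC, RPA
MOL000449	Stigmasterol	43.83	0.76	RRP, RAS, RAB, FC
MOL000358	Beta-sitosterol	36.91	0.75	RAS, RD, RAB, FC, CE, RPA
MOL003152	Gentisin	64.06	0.21	RD
MOL009312	(E,E)-3,5-Di-O-caffeoylquinic acid	48.14	0.68	RD
MOL009317	Cauloside A_qt	43.32	0.81	RD
MOL008188	Japonine	44.11	0.25	RD
MOL009322	Sylvestroside III	48.02	0.53	RD
MOL009323	Sylvestroside III_qt	56.47	0.43	RD
MOL001006	Poriferasta-7,22E-dien-3beta-ol	42.98	0.76	RAB
MOL012461	28-norolean-17-en-3-ol	35.93	0.78	RAB
MOL012505	Bidentatoside, ii_qt	31.76	0.59	RAB
MOL012537	Spinoside A	41.75	0.4	RAB
MOL012542	β-ecdysterone	44.23	0.82	RAB
MOL001454	Berberine	36.86	0.78	RAB
MOL001458	Coptisine	30.67	0.86	RAB
MOL000173	Wogonin	30.68	0.23	RAB
MOL002643	Delta 7-stigmastenol	37.42	0.75	RAB
MOL002714	Baicalein	33.52	0.21	RAB
MOL002776	Baicalin	40.12	0.75	RAB
MOL002897	Epiberberine	43.09	0.78	RAB
MOL003847	Inophyllum E	38.81	0.85	RAB
MOL004355	Spinasterol	42.98	0.76	RAB
MOL000785	Palmatine	64.6	0.65	RAB
MOL000085	Beta-daucosterol_qt	36.91	0.75	RAB
MOL000422	Kaempferol	41.88	0.24	RAB, CE, RPA
MOL000098	Quercetin	46.43	0.28	RAB, CE
MOL000273	(2R)-2-[(3S,5R,10S,13R,14R,16R,17R)-3,16-dihydroxy-4,4,10,13,14-pentamethyl-2,3,5,6,12,15,16,17-octahydro-1H-cyclopenta[a] phenanthren-17-yl]-6-methylhept-5-enoic acid	30.93	0.81	P
MOL000275	Trametenolic acid	38.71	0.8	P
MOL000276	7,9(11)-dehydropachymic acid	35.11	0.81	P
MOL000279	Cerevisterol	37.96	0.77	P
MOL000280	(2R)-2-[(3S,5R,10S,13R,14R,16R,17R)-3,16-dihydroxy-4,4,10,13,14-pentamethyl-2,3,5,6,12,15,16,17-octahydro-1H-cyclopenta[a] phenanthren-17-yl]-5-isopropyl-hex-5-enoic acid	31.07	0.82	P
MOL000282	Ergosta-7,22E-dien-3beta-ol	43.51	0.72	P
MOL000283	Ergosterol peroxide	40.36	0.81	P
MOL000285	(2R)-2-[(5R,10S,13R,14R,16R,17R)-16-hydroxy-3-keto-4,4,10,13,14-pentamethyl-1,2,5,6,12,15,16,17-octahydrocyclopenta[a]phenanthren-17-yl]-5-isopropyl-hex-5-enoic acid	38.26	0.82	P
MOL000287	3beta-hydroxy-24-methylene-8-lanostene-21-oic acid	38.7	0.81	P
MOL000289	Pachymic acid	33.63	0.81	P
MOL000290	Poricoic acid A	30.61	0.76	P
MOL000291	Poricoic acid B	30.52	0.75	P
MOL000292	Poricoic acid C	38.15	0.75	P
MOL000296	Hederagenin	36.91	0.75	P
MOL000300	Dehydroeburicoic acid	44.17	0.83	P
MOL001798	Neohesperidin_qt	71.17	0.27	PCRV
MOL001803	Sinensetin	50.56	0.45	PCRV
MOL004328	Naringenin	59.29	0.21	PCRV
MOL005100	5,7-dihydroxy-2-(3-hydroxy-4 methoxyphenyl) chroman-4-one	47.74	0.27	PCRV
MOL005828	Nobiletin	61.67	0.52	PCRV
MOL001494	Mandenol	42	0.19	FC
MOL001495	Ethyl linolenate	46.1	0.2	FC
MOL001771	Poriferast-5-en-3beta-ol	36.91	0.75	FC
MOL002879	Diop	43.59	0.39	FC
MOL002883	Ethyl oleate (NF)	32.4	0.19	FC
MOL003137	Leucanthoside	32.12	0.78	FC
MOL005360	Malkangunin	57.71	0.63	FC
MOL005481	2,6,10,14,18-pentamethylicosa-2,6,10,14,18-pentaene	33.4	0.24	FC
MOL005486	3,4-Dehydrolycopen-16-al	46.64	0.49	FC
MOL005489	3,6-Digalloylglucose	31.42	0.66	FC
MOL005503	Cornudentanone	39.66	0.33	FC
MOL005530	Hydroxygenkwanin	36.47	0.27	FC
MOL005531	Telocinobufagin	69.99	0.79	FC
MOL008457	Tetrahydroalstonine	32.42	0.81	FC
MOL000554	Gallic acid-3-O-(6′-O-galloyl)-glucoside	30.25	0.67	FC
MOL005552	Gemin D	68.83	0.56	FC
MOL005557	Lanosta-8,24-dien-3-ol,3-acetate	44.3	0.82	FC
MOL002058	40957-99-1	57.2	0.62	CE
MOL004367	Olivil	62.23	0.41	CE
MOL000443	Erythraline	49.18	0.55	CE
MOL005922	Acanthoside B	43.35	0.77	CE
MOL006709	AIDS214634	92.43	0.55	CE
MOL007059	3-beta-Hydroxymethyllenetanshiquinone	32.16	0.41	CE
MOL000073	Ent-Epicatechin	48.96	0.24	CE
MOL007563	Yangambin	57.53	0.81	CE
MOL009007	Eucommin A	30.51	0.85	CE
MOL009009	(+)-medioresinol	87.19	0.62	CE
MOL009015	(−)-Tabernemontanine	58.67	0.61	CE
MOL009027	Cyclopamine	55.42	0.82	CE
MOL009029	Dehydrodiconiferyl alcohol 4,gamma′-di-O-beta-D-glucopyanoside_qt	51.44	0.4	CE
MOL009030	Dehydrodieugenol	30.1	0.24	CE
MOL009031	Cinchonan-9-al, 6′-methoxy-, (9R)-	68.22	0.4	CE
MOL009038	GBGB	45.58	0.83	CE
MOL009042	Helenalin	77.01	0.19	CE
MOL009047	(+)-Eudesmin	33.29	0.62	CE
MOL009053	4-[(2S,3R)-5-[(E)-3-hydroxyprop-1-enyl]-7-methoxy-3-methylol-2,3-dihydrobenzofuran-2-yl]-2-methoxy-phenol	50.76	0.39	CE
MOL009055	Hirsutin_qt	49.81	0.37	CE
MOL009057	Liriodendrin_qt	53.14	0.8	CE
MOL002773	Beta-carotene	37.18	0.58	CE
MOL008240	(E)-3-[4-[(1R,2R)-2-hydroxy-2-(4-hydroxy-3-methoxy-phenyl)-1-methylol-ethoxy]-3-methoxy-phenyl]acrolein	56.32	0.36	CE
MOL011604	Syringetin	36.82	0.37	CE
MOL000211	Mairin	55.38	0.78	CE, RPA
MOL001910	11alpha,12alpha-epoxy-3beta-23-dihydroxy-30-norolean-20-en-28,12beta-olide	64.77	0.38	RPA
MOL001918	Paeoniflorgenone	87.59	0.37	RPA
MOL001919	(3S,5R,8R,9R,10S,14S)-3,17-dihydroxy-4,4,8,10,14-pentamethyl-2,3,5,6,7,9-hexahydro-1H cyclopenta [a] phenanthrene-15,16-dione	43.56	0.53	RPA
MOL001921	Lactiflorin	49.12	0.8	RPA
MOL001924	Paeoniflorin	53.87	0.79	RPA
MOL001925	Paeoniflorin_qt	68.18	0.4	RPA
MOL001928	Albiflorin_qt	66.64	0.33	RPA
MOL001930	Benzoyl paeoniflorin	31.27	0.75	RPA
MOL000492	(+)-catechin	54.83	0.24	RPA
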