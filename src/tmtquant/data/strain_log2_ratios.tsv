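gi	description	group	uv_space	uv_mars	dark_space	dark_mars	cog	significant
500860925	PTS beta-glucoside transporter subunit EIIBCA	catabolic	-0.689	-1.311	-1.243	-0.787	CTM	0
500860804	PTS beta-glucoside transporter subunit EIIBCA	catabolic	-0.259	-0.378	-0.740	-0.235	CTM	0
500860752	PTS fructose transporter subunit IIA	catabolic	-0.046	-0.509	-0.831	-0.705	CTM	0
500857289	PTS fructose transporter subunit IIB	catabolic	-1.247	-1.819	-1.990	-1.138	CTM	0
500857288	PTS fructose transporter subunit IIC	catabolic	-0.556	-0.483	-1.493	-0.717	CTM	0
500857290	PTS glucose transporter subunit IIA	catabolic	-0.960	-1.063	-1.771	-0.907	CTM	0
500860749	PTS lactose/cellobiose transporter subunit IIA	catabolic	-0.381	-0.294	-0.873	-0.442	CTM	0
500860751	PTS sugar transporter subunit IIB	catabolic	-0.895	-0.963	-1.596	-0.471	CTM	0
489303627	phosphocarrier protein HPr	catabolic	-0.506	-1.019	-0.887	-0.451	CTM	0
494764325	PTS sorbitol transporter subunit IIA	catabolic	0.140	0.480	1.205	0.173	CTM	0
500857502	alpha-ketoacid dehydrogenase subunit beta	catabolic	-0.625	-2.094	-3.439	-2.575	EPC	1
500858738	citrate synthase	catabolic	0.227	-0.688	-1.332	-0.902	EPC	0
495621484	citrate synthase	catabolic	-0.125	-0.775	-1.589	-0.990	EPC	0
500858752	2-oxoglutarate dehydrogenase subunit E1	catabolic	-0.165	-0.346	-1.000	-0.666	EPC	0
500858751	dihydrolipoyllysine-residue succinyltransferase	catabolic	-0.362	-0.676	-1.264	-0.810	EPC	0
489304636	succinate-CoA ligase subunit alpha	catabolic	-0.086	-0.563	-1.168	-0.541	EPC	0
500858441	succinyl-CoA ligase subunit beta	catabolic	0.228	-0.354	-0.929	-0.597	EPC	0
500857504	dihydrolipoyl dehydrogenase	catabolic	-0.770	-1.816	-2.652	-2.276	EPC	0
500859474	phosphoenolpyruvate carboxykinase (ATP)	catabolic	0.375	-0.832	-1.788	-0.960	EPC	0
489303411	cytochrome (ubi)quinol oxidase subunit III	catabolic	-0.296	-0.570	-1.525	-1.170	EPC	0
754202327	cytochrome c-prime	catabolic	0.348	-0.479	-0.641	-0.719	EPC	0
500858340	cytochrome c oxidase subunit I	catabolic	0.028	-0.307	-1.355	-0.653	EPC	0
489304759	cytochrome c oxidase subunit II	catabolic	-0.215	-1.312	-1.443	-1.435	EPC	0
494765503	menaquinol-cytochrome c reductase iron-sulfur subunit	catabolic	0.107	-0.922	-1.095	-0.759	EPC	0
500859318	electron transfer flavoprotein subunit alpha/FixB family protein	catabolic	-0.518	-0.863	-1.327	-0.913	EPC	0
500859319	electron transfer flavoprotein subunit beta	catabolic	-0.560	-0.979	-1.465	-0.925	EPC	1
500858688	(Fe-S)-binding protein	catabolic	-0.639	-0.931	-1.140	-1.195	EPC	1
754202216	NADH-dependent flavin oxidoreductase	catabolic	-0.950	-0.626	-0.749	-0.673	EPC	0
500859322	long-chain fatty acid-CoA ligase	catabolic	-0.062	-0.677	-1.386	-0.756	LTM	0
500859693	3-hydroxyacyl-CoA dehydrogenase	catabolic	-0.281	-0.685	-1.361	-0.736	LTM	0
500857672	nonribosomal peptide synthetase	growth	0.730	0.840	1.157	0.920	SMB	1
500857673	polyketide synthase	growth	0.790	0.813	0.627	0.812	SMB	0
500857674	polyketide synthase	growth	0.879	0.739	0.557	0.793	SMB	0
500857675	polyketide synthase	growth	0.958	0.764	0.472	0.825	SMB	0
500859561	chemotaxis protein	growth	-0.278	0.110	0.655	-0.085	CM	0
500859564	chemotaxis protein	growth	0.232	0.512	1.099	0.424	CM	0
500858269	chemotaxis protein CheV	growth	-0.123	0.007	0.681	-0.116	CM	0
500858470	chemotaxis protein CheW	growth	-0.051	0.150	0.776	0.076	CM	0
500858471	chemotaxis protein CheC	growth	0.046	0.327	0.878	0.054	STM	0
500860007	methyl-accepting chemotaxis protein	growth	0.128	0.392	0.730	0.221	CM	0
500859562	methyl-accepting chemotaxis protein	growth	-0.062	0.111	1.024	0.202	CM	0
500858139	flagellin	growth	0.140	0.263	0.654	0.499	CM	0
500858460	flagellar basal body-associated protein FliL	growth	-0.452	-0.529	1.081	-0.437	CM	0
500858457	flagellar hook assembly protein FlgD	growth	-0.684	-0.846	0.520	-0.669	CM	0
500858451	flagellar motor switch protein FliG	growth	-0.093	0.160	0.614	-0.091	CM	0
500859623	sporulation protein	stress	0.160	0.323	0.775	0.248	CCC	0
500858367	dihydropteridine reductase	stress	-0.550	0.213	0.999	-0.097	CCC	0
754201850	universal stress protein	stress	1.328	0.662	0.664	0.437	STM	0
500858196	organic hydroperoxide resistance protein	stress	-0.146	-0.087	-1.051	-0.329	DM	0
500857905	catalase	stress	-0.393	-0.535	-1.297	-0.844	IIT	0
495622186	cold shock protein	stress	0.562	-0.208	0.872	0.071	Transcription	0
500859389	MarR family transcriptional regulator	stress	1.121	0.122	0.310	-0.082	Transcription	1
500857308	MarR family transcriptional regulator	stress	0.098	0.249	0.884	-0.004	Transcription	0
489304493	ECF RNA polymerase sigma factor SigM	stress	0.055	0.348	0.518	0.535	Transcription	1
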