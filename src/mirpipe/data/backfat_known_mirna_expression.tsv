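name	lw_count	ms_count	lw_ne	ms_ne	log2fc	pvalue	sig
ssc-let-7c	877585	702481	45536.7915	35816.4719	-0.34640941	0
ssc-let-7f	821249	708567	42613.5867	36126.7708	-0.23824517	0
ssc-let-7i	52800	46207	2739.7262	2355.8953	-0.2177563	2.1299E-124
ssc-miR-101a	113825	113897	5906.2373	5807.1161	-0.02441744	5.38434E-05
ssc-miR-103	191974	172479	9961.2915	8793.9592	-0.17981996	0
ssc-miR-106a	472	554	24.4915	28.2461	0.20577055	0.022686026
ssc-miR-107	652	872	33.8315	44.4595	0.39412458	1.1522E-07
ssc-miR-122	392	1678	20.3404	85.554	2.07248726	3.8728E-184	**
ssc-miR-125b	70520	50788	3659.1949	2589.4607	-0.4988746	0
ssc-miR-128	529	597	27.4492	30.4385	0.14913316	0.083386279
ssc-miR-130a	2138	1264	110.9382	64.4459	-0.78359575	1.06424E-54
ssc-miR-133a	126	849	6.538	43.2868	2.72700587	8.7333E-130	**
ssc-miR-135	26	2	1.3491	0.102	-3.72535622	1.3011E-06	**
ssc-miR-136	293	423	15.2034	21.5669	0.50442482	3.59769E-06
ssc-miR-139	1158	1478	60.0872	75.3568	0.32668001	7.08989E-09
ssc-miR-140	11884	11133	616.6459	567.6236	-0.11950771	3.3378E-10
ssc-miR-140*	177156	146169	9192.404	7452.526	-0.30271271	0
ssc-miR-145	5863	6830	304.2238	348.2322	0.19491659	2.99995E-14
ssc-miR-146b	4469	1714	231.8908	87.3895	-1.40791374	4.1842E-289	**
ssc-miR-148a	969529	683978	50307.651	34873.0839	-0.52866387	0
ssc-miR-15a	5238	5325	271.7933	271.4987	-0.0015646	0.955478867
ssc-miR-15b	1074	893	55.7285	45.5302	-0.29159152	7.74903E-06
ssc-miR-16	24506	23734	1271.5858	1210.0941	-0.07150957	5.23792E-08
ssc-miR-17	5703	6089	295.9216	310.4518	0.06915429	0.009280647
ssc-miR-18	287	452	14.8921	23.0455	0.62993786	4.84017E-09
ssc-miR-181a	83735	71712	4344.9048	3656.2851	-0.248946	6.3469E-253
ssc-miR-181b	14048	11933	728.9332	608.4121	-0.26073777	6.49187E-48
ssc-miR-181c	1055	779	54.7426	39.7178	-0.46287825	8.46657E-12
ssc-miR-183	519	1342	26.9303	68.4228	1.34524684	8.87706E-81	**
ssc-miR-184	2248	1273	116.6459	64.9048	-0.84573852	3.25294E-65
ssc-miR-185	4448	4947	230.8012	252.2262	0.12806742	1.72089E-05
ssc-miR-186	28047	37058	1455.3239	1889.4274	0.37660881	9.0493E-241
ssc-miR-196	1747	2974	90.6497	151.6314	0.74219439	1.69018E-67
ssc-miR-199b	261685	229155	13578.5084	11683.6237	-0.2168372	0
ssc-miR-19a	196	188	10.1702	9.5853	-0.08545256	0.561914591
ssc-miR-1a	21904	198062	1136.5713	10098.3259	3.15135605	0	**
ssc-miR-20	13192	17233	684.5164	878.6362	0.36018084	3.7558E-104
ssc-miR-204	10	30	0.5189	1.5296	1.55962599	0.00175365	**
ssc-miR-205	68	108	3.5284	5.5065	0.64212149	0.003710943
ssc-miR-21	710609	587666	36872.615	29962.551	-0.29938928	0
ssc-miR-210	106	125	5.5002	6.3732	0.21253385	0.265328125
ssc-miR-214	2218	2191	115.0893	111.7096	-0.04300053	0.322383625
ssc-miR-215	3618	128	187.7335	6.5262	-4.84629903	0	**
ssc-miR-216	17	28	0.8821	1.4276	0.69457768	0.117088654
ssc-miR-217	58	41	3.0095	2.0904	-0.52574479	0.073374517
ssc-miR-221	1931	1784	100.1972	90.9585	-0.13956182	0.00321048
ssc-miR-224	638	215	33.105	10.9619	-1.59455124	3.44467E-51	**
ssc-miR-23a	9821	9749	509.5994	497.0594	-0.0359453	0.081373414
ssc-miR-24	159722	177278	8287.7754	9038.6395	0.12512072	1.2767E-139
ssc-miR-26a	166868	160083	8658.5725	8161.9407	-0.08521697	5.70634E-64
ssc-miR-27a	68858	54931	3572.9558	2800.6944	-0.3513335	0
ssc-miR-29b	1093	1727	56.7144	88.0523	0.6346456	1.00582E-30
ssc-miR-29c	2009	3691	104.2445	188.1881	0.85220413	3.1889E-105
ssc-miR-30a	311295	234230	16152.7094	11942.376	-0.43568628	0
ssc-miR-30b	4621	6932	239.7779	353.4327	0.55973683	1.41568E-94
ssc-miR-30c	10323	10848	535.6476	553.0927	0.04623713	0.01975291
ssc-miR-32	1273	1498	66.0544	76.3765	0.20947414	0.000136849
ssc-miR-326	16	27	0.8302	1.3766	0.72957858	0.108360144
ssc-miR-34a	1446	1807	75.0311	92.1311	0.29619953	5.39272E-09
ssc-miR-450	1018	679	52.8228	34.6193	-0.60958423	7.00986E-18
ssc-miR-503	647	609	33.572	31.0503	-0.11265128	0.166634817
ssc-miR-7	463	595	24.0245	30.3365	0.33654824	0.000159445
ssc-miR-9-1	1480	1459	76.7954	74.3881	-0.04594805	0.387961957
ssc-miR-9-2	1480	1459	76.7954	74.3881	-0.04594805	0.387961957
ssc-miR-95	1295	1502	67.1959	76.5805	0.18860388	0.000558833
ssc-miR-99b	64674	53630	3355.8532	2734.3621	-0.2954753	1.1759E-270
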