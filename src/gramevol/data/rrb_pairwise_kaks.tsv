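seq_1	seq_2	ka	ks	ratio	mya
OsRRB1	PhRRB5	3.4173	2.6949	1.2681	89.83
OsRRB2	PhRRB1	0.1274	0.5719	0.2227	19.06
OsRRB3	PhRRB2	0.1539	0.6039	0.2548	20.13
OsRRB3	PhRRB3	0.231	0.8917	0.259	29.72
OsRRB4	PhRRB7	0.0883	0.553	0.1598	18.43
OsRRB5	PhRRB2	0.2535	1.02	0.2485	34.00
OsRRB5	PhRRB3	0.1416	0.6974	0.2031	23.25
OsRRB6	PhRRB1	0.3996	1.2841	0.3112	42.80
OsRRB1	SbRRB3	0.1119	0.5629	0.1989	18.76
OsRRB2	SbRRB4	0.1275	0.6276	0.2031	20.92
OsRRB2	SbRRB11	0.5467	1.4756	0.3705	49.19
OsRRB3	SbRRB5	0.1599	0.6731	0.2375	22.44
OsRRB3	SbRRB8	0.2332	0.8747	0.2666	29.16
OsRRB4	SbRRB1	0.0889	0.6128	0.145	20.43
OsRRB5	SbRRB5	0.2487	1.093	0.2275	36.43
OsRRB5	SbRRB8	0.1519	0.7098	0.2141	23.66
OsRRB6	SbRRB4	0.4002	1.117	0.3583	37.23
OsRRB6	SbRRB11	0.5331	1.2526	0.4256	41.75
OsRRB1	SiRRB7	0.1047	0.7002	0.1496	23.34
OsRRB2	SiRRB1	0.1216	0.6481	0.1877	21.60
OsRRB3	SiRRB2	0.1538	0.5902	0.2605	19.67
OsRRB3	SiRRB3	0.2397	0.9709	0.2468	32.36
OsRRB4	SiRRB9	0.0955	0.5807	0.1644	19.36
OsRRB5	SiRRB2	0.2468	0.9818	0.2514	32.73
OsRRB5	SiRRB3	0.1477	0.6568	0.225	21.89
OsRRB6	SiRRB1	0.4103	1.3571	0.3023	45.24
OsRRB1	ZmRRB3	0.1252	0.5894	0.2124	19.65
OsRRB1	ZmRRB6	0.1177	0.5639	0.2088	18.80
OsRRB2	ZmRRB4	0.1255	0.681	0.1843	22.70
OsRRB3	ZmRRB5	0.1815	0.6716	0.2702	22.39
OsRRB3	ZmRRB7	0.247	1.1929	0.2071	39.76
OsRRB4	ZmRRB1	0.0971	0.6635	0.1463	22.12
OsRRB4	ZmRRB9	0.1032	0.639	0.1615	21.30
OsRRB5	ZmRRB5	0.2794	1.1734	0.2381	39.11
OsRRB5	ZmRRB7	0.1647	0.9428	0.1747	31.43
OsRRB6	ZmRRB4	0.4282	1.2706	0.337	42.35
OsRRB1	TaRRB2	0.1006	0.6258	0.1607	20.86
OsRRB4	TaRRB4	0.0777	0.4441	0.1749	14.80
OsRRB4	TaRRB5	0.082	0.4541	0.1805	15.14
OsRRB4	TaRRB6	0.0812	0.4712	0.1723	15.71
OsRRB3	TaRRB17	0.2508	1.249	0.2008	41.63
OsRRB5	TaRRB17	0.1651	0.8753	0.1887	29.18
OsRRB3	TaRRB8	0.1297	0.55	0.2359	18.33
OsRRB5	TaRRB8	0.2573	1.0863	0.2369	36.21
OsRRB1	TaRRB1	0.11	0.6795	0.1619	22.65
OsRRB3	TaRRB15	0.2403	1.1425	0.2103	38.08
OsRRB5	TaRRB15	0.1785	0.8258	0.2161	27.53
OsRRB3	TaRRB16	0.1448	1.4261	0.1015	47.54
OsRRB5	TaRRB16	0.1133	1.0021	0.113	33.40
OsRRB2	TaRRB9	0.123	0.6119	0.2009	20.40
OsRRB6	TaRRB9	0.4317	1.4272	0.3025	47.57
OsRRB3	TaRRB10	0.1363	0.6138	0.222	20.46
OsRRB5	TaRRB10	0.2723	1.2458	0.2185	41.53
OsRRB3	TaRRB12	0.1309	0.588	0.2226	19.60
OsRRB5	TaRRB12	0.2671	1.1259	0.2372	37.53
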