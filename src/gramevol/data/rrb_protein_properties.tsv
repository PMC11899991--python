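gene_id	name	species	length	mw	pi	instability_index	aliphatic_index	gravy
LOC_Os01g67770	OsRRB1	Oryza sativa	582	64813.48	5.04	52.76	83.21	-0.426
LOC_Os02g08500	OsRRB2	Oryza sativa	626	68399.04	6.06	35.29	75.85	-0.602
LOC_Os02g55320	OsRRB3	Oryza sativa	688	74383.99	6.45	49.99	81.35	-0.323
LOC_Os03g12350	OsRRB4	Oryza sativa	691	73807.04	6.06	46.47	75.77	-0.399
LOC_Os06g08440	OsRRB5	Oryza sativa	696	75949.63	6.01	48.51	82.84	-0.406
LOC_Os06g43910	OsRRB6	Oryza sativa	694	76623.66	5.65	46.09	62.13	-0.544
Pahal.A00557	PhRRB1	Panicum hallii	637	69308.4	6.03	38.74	77.43	-0.548
Pahal.A03697	PhRRB2	Panicum hallii	677	73794.06	5.93	50.02	83.81	-0.349
Pahal.F02357	PhRRB3	Panicum hallii	667	72992.9	6.01	49.84	79.24	-0.358
Pahal.D00864	PhRRB4	Panicum hallii	753	81469.49	6.02	43.27	75.27	-0.427
Pahal.E00452	PhRRB5	Panicum hallii	575	64419.32	5.2	44.71	81.17	-0.427
Pahal.I03137	PhRRB6	Panicum hallii	338	38692.6	5.72	45.69	81.63	-0.517
Pahal.B00059	PhRRB7	Panicum hallii	689	73949.03	6.23	48.73	77.85	-0.437
Sobic.001G451000	SbRRB1	Sorghum bicolor	686	73679.76	6.26	49.94	77.76	-0.423
Sobic.001G227900	SbRRB2	Sorghum bicolor	347	39281.32	5.57	45.99	84.55	-0.404
Sobic.003G393300	SbRRB3	Sorghum bicolor	579	64700.22	5.04	45.88	81.3	-0.424
Sobic.004G066600	SbRRB4	Sorghum bicolor	631	68631.82	6.12	39.97	77.4	-0.533
Sobic.004G330900	SbRRB5	Sorghum bicolor	675	73136.19	5.96	46.1	80.99	-0.341
Sobic.005G050700	SbRRB6	Sorghum bicolor	694	75483.58	5.78	39.05	77.8	-0.45
Sobic.008G071200	SbRRB7	Sorghum bicolor	551	60852.22	5.66	36.22	80.69	-0.536
Sobic.010G064700	SbRRB8	Sorghum bicolor	672	72886.35	6.01	46.69	80.45	-0.331
Sobic.010G191900	SbRRB9	Sorghum bicolor	671	72439.25	6.71	45.97	73.53	-0.395
Sobic.010G192200	SbRRB10	Sorghum bicolor	668	72765.06	6.58	42.33	77.65	-0.354
Sobic.010G208100	SbRRB11	Sorghum bicolor	531	58488.74	6.08	44.59	71.02	-0.522
Seita.1G061200	SiRRB1	Setaria italica	634	69271.5	6.16	44.78	76.28	-0.578
Seita.1G351300	SiRRB2	Setaria italica	679	73556.54	6.24	46.58	79.25	-0.38
Seita.4G050700	SiRRB3	Setaria italica	666	72711.52	6.13	45.16	79.07	-0.321
Seita.4G198500	SiRRB4	Setaria italica	696	74927.51	6.06	49.66	71.29	-0.41
Seita.4G198600	SiRRB5	Setaria italica	696	74956.4	6.02	50.71	71.29	-0.415
Seita.4G215900	SiRRB6	Setaria italica	701	75701.3	5.46	38.48	71.37	-0.485
Seita.5G419200	SiRRB7	Setaria italica	578	64841.78	5.12	48.87	82.92	-0.433
Seita.9G231000	SiRRB8	Setaria italica	332	38099.01	5.76	40.24	81.33	-0.502
Seita.9G485100	SiRRB9	Setaria italica	687	73746.87	6.38	49.82	76.26	-0.432
Zm00001d028265	ZmRRB1	Zea mays	700	75325.64	6.16	49.28	77.86	-0.38
Zm00001d032784	ZmRRB2	Zea mays	337	38292.12	5.32	45.25	82.43	-0.465
Zm00001d042463	ZmRRB3	Zea mays	615	69249.43	5.13	45.98	80.93	-0.424
Zm00001d015521	ZmRRB4	Zea mays	631	68637.9	6.25	37.13	80.02	-0.493
Zm00001d018380	ZmRRB5	Zea mays	616	66308.81	6.13	47.92	83.57	-0.25
Zm00001d012128	ZmRRB6	Zea mays	603	66962.82	5.04	45.1	81.92	-0.4
Zm00001d045112	ZmRRB7	Zea mays	669	72502.03	5.91	45.11	81.08	-0.311
Zm00001d046755	ZmRRB8	Zea mays	671	73467.82	7.18	44.91	79.57	-0.406
Zm00001d048046	ZmRRB9	Zea mays	686	74002.02	6.12	45.98	77.03	-0.435
TraesCS3A02G391600	TaRRB1	Triticum aestivum	519	57469.68	5.3	57.46	71.75	-0.501
TraesCS3B02G423600	TaRRB2	Triticum aestivum	558	61882.04	5.46	52.54	77.03	-0.417
TraesCS3D02G384500	TaRRB3	Triticum aestivum	491	54106.03	5.57	56.22	73.65	-0.47
TraesCS4A02G063100	TaRRB4	Triticum aestivum	684	73659.79	6.2	47.16	75.28	-0.436
TraesCS4B02G240100	TaRRB5	Triticum aestivum	684	73606.65	6.16	47.1	75.41	-0.434
TraesCS4D02G239900	TaRRB6	Triticum aestivum	684	73603.69	6.16	47.52	75.15	-0.443
TraesCS6A02G146200	TaRRB7	Triticum aestivum	619	67064.32	6.11	36.97	72.6	-0.606
TraesCS6A02G359200	TaRRB8	Triticum aestivum	676	72702.61	6.17	50.36	77.35	-0.322
TraesCS6B02G174400	TaRRB9	Triticum aestivum	591	64329.17	6.02	39.71	71.12	-0.609
TraesCS6B02G392000	TaRRB10	Triticum aestivum	616	66160.07	5.91	50.9	75.55	-0.348
TraesCS6D02G135500	TaRRB11	Triticum aestivum	624	67472.72	6.11	39.16	72.8	-0.61
TraesCS6D02G342200	TaRRB12	Triticum aestivum	617	66248.1	5.87	52.72	75.27	-0.359
TraesCS7A02G146500	TaRRB13	Triticum aestivum	258	29667.3	6.76	42.28	92.52	-0.443
TraesCS7A02G146700	TaRRB14	Triticum aestivum	659	72307.75	5.84	46.41	82.29	-0.341
TraesCS7A02G146400	TaRRB15	Triticum aestivum	618	68018.19	6.52	42.19	83.79	-0.332
TraesCS7B02G049000	TaRRB16	Triticum aestivum	284	32613.36	6.73	36.72	87.11	-0.582
TraesCS7D02G148000	TaRRB17	Triticum aestivum	601	66309.09	5.81	42.68	82.95	-0.363
TraesCS7D02G148200	TaRRB18	Triticum aestivum	659	72017.68	5.92	49.59	84.07	-0.311
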