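group	n_genes	omega_m0	two_dlnl_m3_vs_m0	two_dlnl_m8_vs_m7	two_dlnl_m8_vs_m8a	m8_p1	m8_omega_s	m8_beta_p	m8_beta_q	selected_sites
OGC1	12	0.4033	199.6352	1.0967	-2.2265	0.0000	1.0000	0.2460	1.0868	NAN
OGC2	8	0.2076	62.7116	-0.0001	0.7052	0.0000	1.0000	0.3902	1.2106	NAN
OGC3	8	0.2758	111.4799	-0.0022	0.2532	0.0000	2.6422	0.4916	1.0399	NAN
OGC4	11	0.1082	45.3988	-0.0006	2.4848	0.0000	1.0000	0.1741	1.0287	NAN
OGC5	8	0.2206	69.5820	0.8325	0.0546	0.0816	1.0000	0.4221	1.7059	NAN
OGC6	9	0.2023	96.9320	-0.0001	1.0639	0.0000	1.0000	0.2726	0.8832	NAN
OGC7	4	0.2902	29.8178	-0.0002	7.8491	0.0044	998.9998	0.3026	0.6254	NAN
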