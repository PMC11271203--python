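component_id	region	5	8	14	36	38	76	82	101	102	105	111	113	printed_sum
80	B. Mid. Temp.	58.57	50.32	51.55	54.78	43.05	55.04	55.69	43.02	60.87	53.94	56.50	51.90	635.28
3	B. Post central	56.22	53.89	51.97	53.19	43.10	46.05	47.94	44.60	54.11	58.58	57.76	52.34	619.80
16	B. Post central	46.90	52.43	49.59	45.51	46.13	44.18	46.14	45.29		59.39	60.36	58.59	554.56
97	B. IFG, pars triangularis		47.72	46.87	45.10		47.70	45.29	42.58	48.98	57.8	52.39	55.77	490.23
112	B. precuneus		45.78	44.01	53.09	37.56				51.79		53.91	48.70	334.88
65	B. Mid. Fron.			46.89	45.93	42.80		47.14	38.94		51.50	48.90		322.12
57	R. Post central	47.02	43.58		45.03		46.66		48.46				47.75	278.53
1	B. WM					38.22			44.14	54.97		57.01	47.42	241.78
27	B. Putamen	54.02	46.21	43.51			47.37				48.08			239.22
60	L. Post central							51.35	43.55				52.21	147.11
94	B. Fron. pole			44.60					39.02				55.97	139.60
64	R. Lat. Occ.			42.44					41.46				49.36	133.27
4	L. Post central				44.07	38.76			40.32					123.17
106	B. Mid. Temp.												50.64	50.64
66	B. Fron. pole			50.08										50.08
39	B. Occ. Pole												49.72	49.72
85	B. Fron. pole										49.02			49.02
69	B. Post central	47.12												47.12
6	B. Intracalcarine						44.94							44.94
81	B. Precentral					44.75								44.75
40	B. Tem. Pole			44.57										44.57
11	B. Sup. Fron.				44.32									44.32
52	B. SMA				43.99									43.99
50	B. Cerebellum			42.52										42.52
49	R. Cerebellum					40.00								40.00
29	B. Lat. Occ.					38.84								38.84
12	B. Med. Fron.					38.05								38.05
86	R. IFG, pars triangularis					37.92								37.92
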