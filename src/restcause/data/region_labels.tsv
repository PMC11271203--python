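component_id	region	class
5	Left lateral occipital	cortical
8	Right lateral occipital	cortical
14	Frontal pole	cortical
36	Precuneous	cortical
38	Supramarginal gyrus	cortical
76	Fusiform	cortical
82	Brain stem	subcortical
101	Amygdala	subcortical
102	Thalamus	subcortical
105	Brain stem	subcortical
111	Brain stem	subcortical
113	Brain stem	subcortical
80	B. Mid. Temp.	cortical
3	B. Post central	cortical
16	B. Post central	cortical
97	B. IFG, pars triangularis	cortical
112	B. precuneus	cortical
65	B. Mid. Fron.	cortical
57	R. Post central	cortical
1	B. WM	subcortical
27	B. Putamen	subcortical
60	L. Post central	cortical
94	B. Fron. pole	cortical
64	R. Lat. Occ.	cortical
4	L. Post central	cortical
106	B. Mid. Temp.	cortical
66	B. Fron. pole	cortical
39	B. Occ. Pole	cortical
85	B. Fron. pole	cortical
69	B. Post central	cortical
6	B. Intracalcarine	cortical
81	B. Precentral	cortical
40	B. Tem. Pole	cortical
11	B. Sup. Fron.	cortical
52	B. SMA	cortical
50	B. Cerebellum	subcortical
49	R. Cerebellum	subcortical
29	B. Lat. Occ.	cortical
12	B. Med. Fron.	cortical
86	R. IFG, pars triangularis	cortical
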