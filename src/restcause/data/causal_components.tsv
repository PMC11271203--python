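component_id	score	region	class
111	4413.199227	Brain stem	subcortical
113	4394.348625	Brain stem	subcortical
102	4310.135885	Thalamus	subcortical
5	4251.518294	Left lateral occipital	cortical
105	4236.337062	Brain stem	subcortical
36	3961.601966	Precuneous	cortical
82	3930.660176	Brain stem	subcortical
14	3891.952879	Frontal pole	cortical
8	3820.364736	Right lateral occipital	cortical
101	3618.445033	Amygdala	subcortical
38	3603.503652	Supramarginal gyrus	cortical
76	3542.151380	Fusiform	cortical
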