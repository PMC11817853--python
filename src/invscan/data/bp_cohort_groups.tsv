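region	sample_size	lineage	data_type
Northern Territory, Australia	6	AUS+NG	WGS
Queensland, Australia	6	AUS+NG	WGS
Papua New Guinea	5	AUS+NG	WGS
Indonesia (unknown A)	5	SEA	WGS
Indonesia (wild-caught)	5	SEA	WGS
Indonesia (unknown B)	1	SEA	WGS
Philippines	5	SEA	WGS
Vietnam	2	SEA	WGS
Cambodia	5	SEA	WGS
Thailand	7	SEA	WGS
Bangladesh	2	IND	WGS
India Eastern Coast	7	IND	WGS
India Western Coast	4	IND	WGS
Australia East AUE	14	AUS+NG	RAD
Australia West AUW	22	AUS+NG	RAD
Papua New Guinea PNG	18	AUS+NG	RAD
Indonesia INA	24	SEA	RAD
Malaysia MAL	23	SEA	RAD
Thailand THA	29	SEA	RAD
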