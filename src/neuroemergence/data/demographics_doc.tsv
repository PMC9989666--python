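Sex	Age	Aetiology	Diagnosis	CRS-R Score	Scan
M	46	TBI	UWS	6	12 dir
M	57	TBI	MCS	12	12 dir
M	46	TBI	MCS	10	Not available
M	35	Anoxic	UWS	8	12 dir
M	17	Anoxic	UWS	8	12 dir
F	31	Anoxic	MCS	10	12 dir
F	38	TBI	MCS	11	12 dir
M	29	TBI	MCS	10	63 dir
M	23	TBI	MCS	7	63 dir
F	70	Cerebral bleed	MCS	9	63 dir
F	30	Anoxic	MCS	9	63 dir
F	36	Anoxic	UWS	8	63 dir
M	22	Anoxic	UWS	7	63 dir
M	40	Anoxic	UWS	7	63 dir
F	62	Anoxic	UWS	7	63 dir
M	46	Anoxic	UWS	5	63 dir
M	21	TBI	MCS	11	63 dir
M	67	TBI	MCS	11	63 dir
F	55	Hypoxia	UWS	7	63 dir
M	28	TBI	MCS	8	63 dir
M	22	TBI	MCS	10	63 dir
F	28	ADEM	UWS	6	63 dir
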