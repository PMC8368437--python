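patient	gender	age_years	onset_age_years	seizure_duration_s	follow_up_months	initial_aed	aeds_added	seizure_free	reported_group
1	F	8	6	16.5	12	VPA	N	Y	responder
2	F	9	6	10	23	LTG	N	Y	responder
3	F	8	5	7.1	20	LTG	N	Y	responder
4	F	9	6	7.2	20	LTG	N	Y	responder
5	F	10	8	14.4	20	LTG	N	Y	responder
6	F	13	7	15	68	LTG	N	Y	responder
7	F	11	5	15.5	74	VPA	N	Y	responder
8	F	8	6	5	23	LTG	N	Y	responder
9	F	13	7	14.8	68	LTG	N	Y	responder
10	F	8	7	24	13	LTG	N	Y	responder
11	M	6	5	10.2	14	VPA	N	Y	responder
12	F	7	6	14.7	13	LTG	N	Y	responder
13	M	8	7	18	12	VPA	N	Y	responder
14	M	14	6	20	24	VPA	N	N	nonresponder
15	F	15	8	18.5	25	LTG	VPA	Y	nonresponder
16	F	9	7	9.3	12	LTG	N	N	nonresponder
17	F	10	8	15	26	VPA	N	N	nonresponder
18	F	10	5	11.2	15	VPA	N	N	nonresponder
19	F	11	10	11.3	12	LTG	N	N	nonresponder
20	F	14	4	11.3	67	LTG	VPA	Y	nonresponder
21	M	11	6	18	23	LTG	VPA	Y	nonresponder
22	F	11	5	13	13	VPA	N	N	nonresponder
23	M	7	5	20.5	19	VPA	N	N	nonresponder
24	F	17	6	18	72	LTG	VPA	Y	nonresponder
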