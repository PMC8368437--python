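region	1-4_N	1-4_R	4-8_N	4-8_R	8-12_N	8-12_R	12-30_N	12-30_R	30-80_N	30-80_R	80-250_N	80-250_R
FC	4	3	4	1	7	0	3	2	10	1	3	1
MFC	3	3	4	1	7	0	3	2	5	0	3	0
LFL	1	0	0	0	0	0	0	0	5	1	0	1
TC	1	0	1	0	1	2	0	2	0	3	3	6
TPJ	1	2	0	0	0	3	0	1	0	0	0	1
POT	6	5	4	2	2	2	3	2	0	0	0	0
Pc	0	3	1	0	0	1	2	3	1	1	0	0
PCC	0	2	0	0	0	0	2	0	0	1	0	0
PL	1	1	2	1	2	1	1	0	0	0	0	0
MOC	2	4	0	2	1	2	1	2	0	1	0	0
TH	0	3	1	4	1	1	3	3	2	7	1	1
CE	0	0	1	0	0	0	0	0	0	0	1	2
DBA	0	1	0	2	0	2	1	0	3	1	4	3
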