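population	basin	H1	H2	H3	H4	H5	H6	H7	H8	H9	H10	H11	H12	H13	N
A1	Nenjiang	6	0	1	2	0	0	0	0	1	0	0	0	0	10
A2	Nenjiang	5	1	2	2	0	0	0	0	0	0	0	0	0	10
A3	Nenjiang	2	8	0	0	0	0	0	0	0	0	0	0	0	10
A4	Nenjiang	4	1	1	4	0	0	0	0	0	0	0	0	0	10
B1	Songhua	12	6	4	8	0	0	0	0	1	0	0	0	0	31
C1	Yellow	8	1	1	0	0	0	0	0	0	0	0	0	0	10
C2	Yellow	4	0	1	3	1	0	0	0	0	0	0	0	0	9
D1	Yangtze	0	6	5	13	0	1	4	1	0	0	0	0	0	30
E1	Lancang	8	4	0	11	0	0	0	0	0	0	0	0	0	23
E2	Lancang	4	5	2	12	0	0	0	0	0	1	0	0	0	24
F1	Huaihe	6	6	2	12	0	0	0	0	0	1	1	1	1	30
Entire_region	-	59	38	19	67	1	1	4	1	2	2	1	1	1	197
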