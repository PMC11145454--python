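	Doublet	Singlet0	Singlet1	Singlet2	Singlet3	Singlet4	Singlet5	Singlet6	Singlet7	Unassigned
Doublet	1173	166	80	88	103	70	82	51	75	5
Negative	4	31	4	49	8	28	23	17	6	0
S282	54	0	0	0	0	1	0	210	51	1
S283	20	0	1	1	1748	0	0	1	0	0
S284	9	0	0	1492	0	1	0	0	0	0
S344	21	0	1528	0	1	2	0	8	0	0
S397	8	2046	0	0	0	0	0	1	0	0
S417	15	0	0	0	1	1153	1	2	0	2
S421	4	0	0	0	0	0	0	0	776	0
S423	18	0	0	0	0	0	1644	0	0	0
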