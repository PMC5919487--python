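#id	size	edges	orbits	redundancy
0	2	0-1	0,0	0
1	3	0-1,0-2	2,1,1	0
2	3	0-1,0-2,1-2	3,3,3	1
3	4	0-1,0-2,0-3	5,4,4,4	0
4	4	0-1,0-3,1-2	7,7,6,6	0
5	4	0-1,0-2,0-3,1-2	10,9,9,8	1
6	4	0-2,0-3,1-2,1-3	11,11,11,11	1
7	4	0-1,0-2,0-3,1-2,1-3	13,13,12,12	2
8	4	0-1,0-2,0-3,1-2,1-3,2-3	14,14,14,14	3
9	5	0-1,0-2,0-3,0-4	16,15,15,15,15	0
10	5	0-1,0-3,0-4,1-2	20,19,17,18,18	0
11	5	0-2,0-4,1-2,1-3	22,22,23,21,21	0
12	5	0-1,0-2,0-3,0-4,1-2	26,25,25,24,24	1
13	5	0-1,0-2,0-4,1-2,1-3	29,29,28,27,27	1
14	5	0-2,0-3,0-4,1-2,1-3	33,31,32,32,30	1
15	5	0-1,0-4,1-2,1-3,2-3	35,37,36,36,34	1
16	5	0-3,0-4,1-2,1-4,2-3	38,38,38,38,38	1
17	5	0-1,0-2,0-3,0-4,1-2,1-3	42,41,40,40,39	2
18	5	0-2,0-3,0-4,1-2,1-3,1-4	44,44,43,43,43	2
19	5	0-1,0-2,0-4,1-2,1-3,2-3	47,48,48,46,45	2
20	5	0-1,0-2,0-3,0-4,1-4,2-3	50,49,49,49,49	2
21	5	0-1,0-3,0-4,1-2,1-4,2-3	53,53,51,51,52	2
22	5	0-1,0-2,0-3,0-4,1-2,1-3,1-4	55,55,54,54,54	3
23	5	0-1,0-2,0-3,0-4,1-2,1-3,2-3	58,57,57,57,56	3
24	5	0-1,0-2,0-3,0-4,1-2,1-4,2-3	61,60,60,59,59	3
25	5	0-2,0-3,0-4,1-2,1-3,1-4,2-3	63,63,64,64,62	3
26	5	0-1,0-2,0-3,0-4,1-2,1-3,1-4,2-3	67,67,66,66,65	4
27	5	0-1,0-2,0-3,0-4,1-3,1-4,2-3,2-4	69,68,68,68,68	4
28	5	0-1,0-2,0-3,0-4,1-2,1-3,1-4,2-3,2-4	71,71,71,70,70	5
29	5	0-1,0-2,0-3,0-4,1-2,1-3,1-4,2-3,2-4,3-4	72,72,72,72,72	6
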