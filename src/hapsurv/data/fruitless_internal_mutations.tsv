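mutation	effect	f	published_rank
6	synonymous	3	7.5
8	synonymous	3	7.5
35	synonymous	3	7.5
39	synonymous	3	7.5
46	synonymous	3	7.5
47	synonymous	3	7.5
49	synonymous	3	7.5
55	synonymous	3	7.5
61	synonymous	3	7.5
62	synonymous	3	7.5
63	synonymous	3	7.5
4	synonymous	3	7.5
5	synonymous	3	7.5
48	synonymous	3	7.5
2	synonymous	4	20.5
14	synonymous	4	20.5
18	synonymous	4	20.5
29	synonymous	4	20.5
36	synonymous	4	20.5
37	synonymous	4	20.5
43	synonymous	4	20.5
44	synonymous	4	20.5
45	synonymous	4	20.5
60	synonymous	4	20.5
64	synonymous	4	20.5
19	nonsynonymous	4	20.5
17	synonymous	5	28
42	synonymous	5	28
54	synonymous	5	28
7	synonymous	6	31
41	synonymous	6	31
12	nonsynonymous	6	31
40	synonymous	7	33
52	synonymous	10	34
11	synonymous	11	36
9	nonsynonymous	11	36
10	nonsynonymous	11	36
1	synonymous	12	38
34	synonymous	53	39
31	nonsynonymous	55	40
26	nonsynonymous	59	42
27	nonsynonymous	59	42
28	nonsynonymous	59	42
25	nonsynonymous	60	44
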