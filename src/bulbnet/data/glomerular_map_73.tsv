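id	cluster	x_mm	y_mm
0	A	0.7962189875920536	0.0342868644968462
1	A	0.8338232001789171	0.10825418226930539
2	A	0.7426595339492789	0.16231660920449514
3	A	0.8027829282782265	0.24942856356309923
4	A	0.719404534021107	0.29346317259931265
5	A	0.7014372839086347	0.3593034207899181
6	A	0.7022257726354002	0.4397337144019682
7	A	0.6283954424826882	0.4732944192741952
8	A	0.595829386862435	0.5349415065160295
9	A	0.5119346333382725	0.5460961732352025
10	A	0.5080071909630621	0.6451175435851346
11	A	0.4388488178475649	0.6683968572686365
12	A	0.36986714385255326	0.6853076444748648
13	A	0.3278207957667403	0.7566555944928333
14	A	0.24617031885342255	0.7360179202221315
15	A	0.18551188436172628	0.7690665265337194
16	A	0.11391889003116347	0.7505831507591827
17	A	0.0507091899036547	0.7844487233908456
18	B	-0.016483917721526745	0.7659428842084757
19	B	-0.08289904922858365	0.7675422386469992
20	B	-0.15796641061428954	0.8054673244768638
21	B	-0.21364814248198435	0.7437372119828958
22	B	-0.2841174979913226	0.7417411331121966
23	B	-0.3684674589188987	0.7591521018292129
24	B	-0.4313862095197426	0.7230281004435024
25	B	-0.4781041480470073	0.6640448454668015
26	B	-0.521452312527162	0.6065668453759891
27	B	-0.5527740185587117	0.5410057206683929
28	B	-0.5882597077338988	0.4840976909479935
29	B	-0.6943753313611242	0.477597684562491
30	B	-0.6933945560233039	0.39372752539632216
31	B	-0.6883032861088798	0.315966279508271
32	B	-0.7607008250431515	0.27276025142148164
33	B	-0.7961440901806919	0.21026889025775503
34	B	-0.7951465625514859	0.13824642214520066
35	B	-0.8344041908401412	0.07199590457541757
36	C	-0.749734003125897	9.181593471400614e-17
37	C	-0.7956772397522519	-0.06865438028104286
38	C	-0.7800069395382812	-0.13561420462358204
39	C	-0.7270789085121198	-0.19202814805541724
40	C	-0.7623799858071917	-0.2733623387297878
41	C	-0.7552619910700281	-0.34670373683884587
42	C	-0.7000793011917353	-0.3975232981640895
43	C	-0.6358909722723088	-0.4373716090923463
44	C	-0.6407068617613833	-0.5272581281285456
45	C	-0.5693976558048419	-0.5572754485255778
46	C	-0.5194745832386984	-0.6042662994071788
47	C	-0.47975422168592596	-0.6663366534317404
48	C	-0.3896927463256506	-0.6531474579266814
49	C	-0.361432549931817	-0.7446581056446127
50	C	-0.2912033545756404	-0.7602400686901905
51	C	-0.2276376498607428	-0.7924365224193051
52	C	-0.14721320900199789	-0.7506369811239229
53	C	-0.08869818766788995	-0.8212350583035429
54	C	-0.016457815866790026	-0.7647300335841123
55	D	0.04863485382226162	-0.7523596623345705
56	D	0.12474066443381526	-0.8218851229406685
57	D	0.19507410571784622	-0.8087081073930786
58	D	0.2643562361046178	-0.7903914980559681
59	D	0.31523781099665144	-0.7276123307809101
60	D	0.3672224582250109	-0.6804074436651661
61	D	0.40970243106574517	-0.6240049105812661
62	D	0.5013383949891357	-0.6366488499250831
63	D	0.5592858129784436	-0.5966071102098132
64	D	0.6171089386331473	-0.5540464982019117
65	D	0.6182252789465102	-0.46563446294834754
66	D	0.6503152110127242	-0.4072273254761334
67	D	0.7206623184405889	-0.3691512301815773
68	D	0.7650733089494851	-0.31209261256724724
69	D	0.8042174244943673	-0.24987426852022382
70	D	0.7432813765680333	-0.16245251991555637
71	D	0.787387779950685	-0.10222553201819658
72	D	0.8344729597424512	-0.035934161007010905
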