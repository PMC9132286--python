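region	residue_number	active_site_distance	native_aa	has_interaction_potential	designed_aa	ddG
2	48	51.2	E	Yes	E	-
2	49	52.8	S	Yes	E	-2.4
2	50	53.0	E	No	-	-
2	51	55.0	Q	No	-	-
2	52	52.8	P	Yes	L	-3.8
2	53	50.7	I	Yes	I	-
2	54	49.5	Y	Yes	F	3.2
2	55	52.9	F	Yes	V	-3.7
2	56	48.4	E	Yes	H	-6.1
2	57	51.5	P	Yes	G	-5.7
2	58	53.8	D	Yes	D	-
2	59	49.2	E	Yes	E	-
2	60	49.9	L	Yes	L	-
2	61	47.3	Y	Yes	L	3.8
2	62	43.0	E	Yes	M	1.4
2	63	40.9	N	Yes	W	1.0
2	64	38.2	N	Yes	G	-5.9
2	65	37.6	A	Yes	A	-
2	66	41.3	F	Yes	W	2.7
2	67	43.1	K	Yes	H	-4.5
2	68	41.4	I	Yes	M	3.1
2	69	45.2	N	Yes	W	-4.3
2	70	45.0	M	Yes	M	-
3	83	49.9	G	Yes	G	-
3	84	53.4	V	Yes	V	-
3	85	57.2	R	Yes	R	-
3	86	59.6	N	No	-	-
3	87	59.9	D	No	-	-
3	88	55.3	N	Yes	Q	-6.5
3	89	57.8	E	Yes	E	-
3	90	52.3	V	Yes	V	-
3	91	51.0	T	Yes	I	-5.4
3	92	49.9	S	Yes	S	-
3	93	46.0	S	Yes	A	-4.1
4	201	21.9	G	Yes	G	-
4	202	19.7	N	Yes	V	-2.1
4	203	18.5	L	Yes	L	-
4	204	15.2	G	Yes	G	-
4	205	16.8	F	Yes	F	-
4	206	14.2	D	Yes	-	-
4	207	18.5	G	Yes	D	-1.6
4	208	22.2	G	Yes	G	-
4	209	22.0	Q	Yes	M	-1.5
4	210	22.6	T	Yes	S	-2.6
4	211	20.4	N	Yes	T	-3.5
4	212	24.1	I	Yes	T	-2.2
4	213	26.5	Y	Yes	K	-7.9
4	214	26.4	G	Yes	G	-
8	561	16.7	N	Yes	A	1.0
8	562	15.6	G	Yes	W	0.1
8	563	14.4	A	Yes	-	-
8	564	10.5	N	Yes	-	-
8	565	13.9	P	No	-	-
8	566	15.4	Q	Yes	Q	-
8	567	19.1	G	No	A	1.3
8	568	19.8	K	Yes	Q	-2.7
8	569	23.7	T	Yes	G	-4.8
11	716	12.0	S	Yes	-	-
11	717	16.3	V	Yes	V	-
11	718	16.8	L	Yes	L	-
11	719	19.8	P	Yes	H	-0.8
11	720	18.6	D	Yes	D	-
11	721	14.5	G	Yes	-	-
11	722	14.2	K	Yes	-	-
11	723	8.9	M	Yes	-	-
11	724	11.2	N	Yes	-	-
11	725	11.9	P	No	-	-
11	726	8.6	E	Yes	-	-
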