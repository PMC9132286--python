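region	mutant	mean_500K	sem_500K	mean_313K	sem_313K
2	S49E	-2.5	5.8	-	-
2	P52L	6.7	5.2	-	-
2	F55V	0.2	4.7	-	-
2	E56H	3.3	5.8	-	-
2	P57G	14.0	5.9	-	-
2	N64G	-9.1	4.7	-	-
2	K67H	14.7	4.6	-	-
2	N69W	14.9	6.8	-	-
3	N88Q	-18.9	7.1	-13.6	10.2
3	T91I	-0.8	4.7	-	-
3	S93A	-0.6	4.1	-	-
4	N202V	-25.4	1.1	-61.4	7.2
4	G207D	-30.6	1.2	-58.0	7.1
4	Q209M	-19.4	3.0	-54.5	5.3
4	T210S	-3.5	2.3	-	-
4	N211T	-13.8	1.6	-56.0	5.2
4	I212T	-3.0	0.9	-	-
4	Y213K	-12.7	0.9	-57.0	5.8
8	K568Q	-15.6	4.0	44.5	16.4
8	T569G	-17.5	4.3	12.8	12.5
11	P719H	15.7	8.9	-	-
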