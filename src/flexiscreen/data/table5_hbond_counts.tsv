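region	system	strong	medium	weak	very_weak
3	Wild type	4	4	5	10
3	N88Q	6	3	5	3
4	Wild type	-	-	3	21
4	N202V	1	3	9	17
4	G207D	-	1	13	15
4	Q209M	-	2	12	17
4	N211T	-	2	12	17
4	Y213K	-	2	7	25
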