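mirna	mature	size	lp	mfe	count_vs	count_rs	total	star_reads	loci
rsa-miRn1	AGAAGAGGAAGAGGATGAAGAT	22	209	-75.8	0	525	525	-	1
rsa-miRn2	AGGGGAGGATGGGTGGGTTTC	21	106	-44.2	0	168	168	-	2
rsa-miRn3	CATTGACTGTATGCATTGGGAG	21	272	-73.2	919	86	1005	1	1
rsa-miRn4	TCGGAATTCCGTCGGAATATA	21	100	-56.31	743	1402	2145	25	1
rsa-miRn5	TACCGATAGATGTGGAAGCGT	21	184	-75.8	2502	4596	7098	41	1
rsa-miRn6	TTTGCGTGAGTATGTGGATGT	21	119	-49	2809	1341	4150	35	1
rsa-miRn7	AGCAAACGAGAATTGAACGGA	21	106	-47.24	842	1018	1860	4	2
rsa-miRn8	ATGGCCTTTATATCGTATTCGAA	23	109	-30.2	0	40	40	8	1
rsa-miRn9	ATGTGGGATGTGATTGTCAAG	21	83	-22.36	112	319	431	-	1
rsa-miRn10	GTGACCGGCGCGTGGCGGCTC	21	74	-36.9	15	9	24	-	1
rsa-miRn11	ATGCCTGGCTCCCTGTATGCC	21	106	-49.3	0	457	457	-	1
rsa-miRn12	GGTAGTTTGACCGCGAAATTT	21	143	-28	6902	11143	18045	-	1
rsa-miRn13	GTCTGTATGGTATGGGTGGAGG	22	110	-52.11	0	19	19	-	1
rsa-miRn14	GCTAATGAGATCGAAATACTGA	21	182	-28.9	0	23	23	1	1
rsa-miRn15	CAGAGACAGAGAGGAGAAAGGAA	23	90	-34	22	28	50	-	2
rsa-miRn16	ATATACTGAAGTTTATACTCT	21	208	-37	0	18	18	-	1
rsa-miRn17	TATGAATGATGCGGGAGATGT	21	112	-33.5	108	17	125	6	1
rsa-miRn18	AGGACCAGGTCGACGACGCCG	21	80	-44.9	312	558	870	98	1
rsa-miRn19	TGAGCGGCAACTATTGTAGGT	21	111	-50.7	14	9	23	-	1
rsa-miRn20	TCTTGAGTTCGAGGGACGCCA	21	107	-65.6	90	153	243	3	1
rsa-miRn21	GTTGGGATCGCTTGTTGGAGT	21	340	-104.4	798	0	798	-	1
rsa-miRn22	AGAAGAACGGGAACAAAGAAA	22	147	-23.6	0	22	22	-	1
rsa-miRn23	ACGAGGCTGTGGCTTACGGTG	21	111	-37.1	0	26	26	1	1
rsa-miRn24	AGGATTGAGTCTAGAAGCATA	21	270	-57.1	127	0	127	-	1
rsa-miRn25	AGAACGATATAAAAGATCATGG	22	107	-30.2	48	0	48	20	1
rsa-miRn26	GAGGGGAGGATGGGTGGGTTTC	22	106	-44.2	82	0	82	-	2
rsa-miRn27	GCGTCCCCGACATGGTCGTCT	21	72	-31.7	0	81	81	5	1
rsa-miRn28	GAAGATTTAGTAGAGTTGGCG	21	113	-27.3	0	37	37	-	1
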