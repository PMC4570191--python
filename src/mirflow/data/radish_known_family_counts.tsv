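family	conservation	members	count_vs	count_rs
miR156/157	conserved	11	266846	150543
miR158	conserved	3	276036	47200
miR159	conserved	4	1998	1746
miR160	conserved	5	15531	25963
miR162	conserved	4	1968	2663
miR164	conserved	2	25738	8908
miR165/166	conserved	9	291809	283516
miR167	conserved	5	407770	82164
miR168	conserved	4	182405	162566
miR169	conserved	3	1829	214
miR171	conserved	1	2940	1276
miR172	conserved	5	80912	26261
miR390	conserved	3	6814	2257
miR391	conserved	2	25775	9225
miR393	conserved	1	22	13
miR395	conserved	1	681	160
miR396	conserved	3	5086	6554
miR397	conserved	1	854	633
miR398	conserved	2	411	30067
miR399	conserved	5	592	1129
miR408	conserved	1	4544	740985
miR1885	non-conserved	2	8337	12369
miR1863	non-conserved	1	9168	2416
miR2111	non-conserved	2	113	638
miR394	non-conserved	3	72	55
miR400	non-conserved	2	130	241
miR403	non-conserved	1	1900	1485
miR535	non-conserved	1	0	2797
miR5161	non-conserved	1	1423	5868
miR5227	non-conserved	1	144	0
miR6273	non-conserved	1	0	360
miR6284	non-conserved	1	163	0
miR824	non-conserved	2	1822	706
miR860	non-conserved	1	212	653
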