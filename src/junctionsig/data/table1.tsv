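patient_code	start_hg19	end_hg19	size_kb	mh_len	scar	repeat_prox	motifs_prox	nonb_prox	repeat_dist	motifs_dist	nonb_dist	identity_pct	mechanism
A	138949150	138956510	7	-	-	-	8	-	-	6	-	-	NHEJ
B	138912808	139012600	100	5	-	L1PA4	6	-	MIRb	10	-	-	Replicative/MMEJ
C	138867472	139048942	181	1	-	L1ME3F	3	-	MIRc	8	-	-	Replicative/NHEJ
D	138479902	138662725	183	2	-	-	4	-	-	7	-	-	Replicative/NHEJ
E	138805920	139012140	206	1	TC>AA	L1M7	7	-	-	11	-	-	Replicative/NHEJ
F	138938973	139294473	356	1	-	L1Med	30	-	-	3	-	-	Replicative/NHEJ
G	138745991	140393036	1647	33	-	L1PA5	9	-	L1PA4	8	-	93	NAHR/Replicative/MMEJ
H	138741281	141762242	3021	12	-	AluSz	8	1	AluSz	17	-	83	NAHR/Replicative/MMEJ
1	138664845	138666255	1	5	-	-	6	3	-	15	1	-	Replicative/MMEJ
2	138658319	138666527	8	4	-	-	5	1	-	5	1	-	Replicative/NHEJ
3	138649686	138736058	86	1	C>A	-	12	1	-	5	-	-	Replicative/NHEJ
4	138661542	138786728	125	1	-	-	-	-	L1PA2	8	-	-	Replicative/NHEJ
5	138475828	138857284	381	1	-	L1MB4	7	-	-	40	1	-	Replicative/NHEJ
6	138019964	139735421	1715	-	del(T)	Tigger15a	2	-	AluSc	6	1	-	NHEJ
7	137894385	139735424	1841	15	-	AluSx3	7	1	AluSc	6	2	85	NAHR/Replicative/MMEJ
8	136887871	138746237	1858	66	-	L1PA3	4	-	L1PA5	4	-	93	NAHR/Replicative/MMEJ
9	138532388	140753510	2221	15	-	AluY	8	-	AluY	14	1	85	NAHR/Replicative/MMEJ
10	136604806	139000361	2396	2	-	-	7	-	-	11	-	-	Replicative/NHEJ
11	136007507	138671922	2664	34	-	AluJo	7	-	AluSz	10	1	77	NAHR/Replicative/MMEJ
12	138134298	141034621	2900	1	-	AluJr	16	-	Charlie1a	7	-	-	Replicative/NHEJ
13	138602856	142458004	3855	26	-	AluSp	9	-	AluSp	12	-	89	NAHR/Replicative/MMEJ
14	137934887	142100431	4166	25	-	AluSx3	36	1	AluSz6	36	1	74	NAHR/Replicative/MMEJ
15	135099979	139713853	4614	1	-	LTR33A	3	-	-	7	-	-	Replicative/NHEJ
16	136887730	142397685	5510	5	-	L1PA3	9	-	L1PA3	6	-	96	NAHR/Replicative/MMEJ
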