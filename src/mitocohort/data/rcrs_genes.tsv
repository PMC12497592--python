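name	start	end	strand	kind	wrap	incomplete_stop
tRNA-Phe	577	647	H	tRNA	0	0
12S rRNA	648	1601	H	rRNA	0	0
tRNA-Val	1602	1670	H	tRNA	0	0
16S rRNA	1671	3229	H	rRNA	0	0
tRNA-Leu(UUR)	3230	3304	H	tRNA	0	0
ND1	3307	4262	H	protein	0	1
tRNA-Ile	4263	4331	H	tRNA	0	0
tRNA-Gln	4329	4400	L	tRNA	0	0
tRNA-Met	4402	4469	H	tRNA	0	0
ND2	4470	5511	H	protein	0	1
tRNA-Trp	5512	5579	H	tRNA	0	0
tRNA-Ala	5587	5655	L	tRNA	0	0
tRNA-Asn	5657	5729	L	tRNA	0	0
tRNA-Cys	5761	5826	L	tRNA	0	0
tRNA-Tyr	5826	5891	L	tRNA	0	0
COX1	5904	7445	H	protein	0	0
tRNA-Ser(UCN)	7446	7514	L	tRNA	0	0
tRNA-Asp	7518	7585	H	tRNA	0	0
COX2	7586	8269	H	protein	0	0
tRNA-Lys	8295	8364	H	tRNA	0	0
ATP8	8366	8572	H	protein	0	0
ATP6	8527	9207	H	protein	0	0
COX3	9207	9990	H	protein	0	1
tRNA-Gly	9991	10058	H	tRNA	0	0
ND3	10059	10404	H	protein	0	1
tRNA-Arg	10405	10469	H	tRNA	0	0
ND4L	10470	10766	H	protein	0	0
ND4	10760	12137	H	protein	0	1
tRNA-His	12138	12206	H	tRNA	0	0
tRNA-Ser(AGY)	12207	12265	H	tRNA	0	0
tRNA-Leu(CUN)	12266	12336	H	tRNA	0	0
ND5	12337	14148	H	protein	0	0
ND6	14149	14673	L	protein	0	0
tRNA-Glu	14674	14742	L	tRNA	0	0
CYTB	14747	15887	H	protein	0	1
tRNA-Thr	15888	15953	H	tRNA	0	0
tRNA-Pro	15956	16023	L	tRNA	0	0
D-loop	16024	576	H	control	1	0
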