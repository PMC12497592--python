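haplogroup	parent	defining_variants
MRCA		
M	MRCA	489_A>G,10400_G>A,14783_C>T
N	MRCA	8701_T>C,9540_A>G,10398_G>A
D	M	4883_C>T,5178_G>A
D4	D	3010_A>G,8414_G>A,14668_A>G
D4a	D4	3206_C>T,14979_T>C
D4b	D4	8020_C>T,15440_T>C
D5	D	1107_A>G,5301_A>G
G	M	709_A>G,4833_C>T,16278_A>G
M7	M	6455_G>A,9824_A>G
M7b	M7	4071_A>G,12811_T>C
Z	M	6752_A>G,9090_A>G,15784_A>G
A	N	663_A>G,1736_A>G,4824_A>G
N9a	N	5417_T>C,12358_A>G
R	N	12705_C>T,16223_C>T
B	R	8281_A>G,16217_G>A
F	R	3970_G>A,6392_A>G,10310_T>C
F1	F	6962_C>T,12406_T>C
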