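# Kinase assignments per site from the curated FoxO3 table.
position	residue	kinases
12	S	ERK1;AKT
26	S	GSK3
43	S	Cdk5
151	S	PKC;PKA
173	S	Cdk5;Cdc2
209	S	PKC
253	S	AKT;PKA
280	S	CK2;GSK3
284	S	ERK
294	S	Cdk5;Cdc2;ERK1;p38 MAPK
300	S	CK2
315	S	AKT;Clk2
318	S	CK1
321	S	CK1
325	S	ERK1
344	S	ERK1
351	S	GSK3
353	S	CK1;PKC;PKC delta
355	S	ERK1;Cdk5
399	S	ATMK;AMPK
402	S	ERK1
413	S	AKT;PKC
421	S	CK1
425	S	Cdc2;Cdk5;GSK3;ERK1
432	S	CK1
463	S	CK1
497	S	PKC
553	S	PKC
567	S	PKC
577	S	ATMK
588	S	AMPK
591	S	PKC;CK1
32	T	AKT;PKA
296	T	PKC
331	T	CK2
417	T	PKC
487	T	DNA PK
582	T	PKC;CK1
162	Y	Lck kinase
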