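# Curated experimentally verified FoxO3 phosphosites (20 Ser, 1 Thr).
# kinases column: experimentally confirmed kinase only (empty if unknown).
position	residue	kinases	source_tag
7	S		Phospho.ELM/Swiss-Prot
12	S		Phospho.ELM/Swiss-Prot
209	S		Phospho.ELM/Swiss-Prot
253	S	AKT	Phospho.ELM/Swiss-Prot
280	S		Phospho.ELM/Swiss-Prot
284	S		Phospho.ELM/Swiss-Prot
294	S	ERK1	Phospho.ELM/Swiss-Prot
299	S		Phospho.ELM/Swiss-Prot
315	S	AKT	Phospho.ELM/Swiss-Prot
318	S	CK1	Phospho.ELM/Swiss-Prot
321	S	CK1	Phospho.ELM/Swiss-Prot
325	S		Phospho.ELM/Swiss-Prot
344	S	ERK1	Phospho.ELM/Swiss-Prot
399	S	AMPK	Phospho.ELM/Swiss-Prot
413	S		Phospho.ELM/Swiss-Prot
421	S		Phospho.ELM/Swiss-Prot
425	S	ERK1	Phospho.ELM/Swiss-Prot
588	S	AMPK	Phospho.ELM/Swiss-Prot
626	S		Phospho.ELM/Swiss-Prot
644	S		Phospho.ELM/Swiss-Prot
32	T	AKT	Phospho.ELM/Swiss-Prot
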