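# Curated FoxO3 methylation sites (4 Arg, 5 Lys) with printed flanks.
position	residue	conserved	flank	ev_note
248	R	True	GKSGKAP*R*RR	sequence similarity with mouse FoxO1 methylation sites
250	R	True	PRR*R*AVSMD	sequence similarity with mouse FoxO1 methylation sites
264	R	True	NKYTKS*R*GRAAKK	
266	R	True	YTKSRG*R*AAKKKA	
149	K	True	GGSGQPR*K*CSSRR	
207	K	True	SNSSAGW*K*NSIRH	
270	K	True	SRGRAAK*K*KAALQ	
271	K	True	SRGRAAKK*K*AALQ	
569	K	True	SSSLGSA*K*HQQQS	
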